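# Methods

## The filter

Non-local means (NLM) denoises a pixel x by a weighted average of other
pixels y,

    p*(x) = Σ_y φ(x, y) p(y),
    φ(x, y) = exp(−Z(V_x, V_y) / α²) / A(x),

where V_x is the (2r+1)×(2r+1) patch around x, Z is the Gaussian-weighted
squared Euclidean distance between the two patches,

    Z(V_x, V_y) = Σ_k G_η(k) · (p(x+k) − p(y+k))²,

and A(x) normalizes the weights to sum to one. In the classic filter the
sum runs over every pixel of the image; the windowed variant (ONLM)
restricts it to a (2s+1)×(2s+1) search window centered on x. That is the
whole difference between the two: with a window at least the image extent
the windowed filter *is* the classic filter, and the implementation makes
this literal by dispatching both through the same code path in that
regime (so the degeneracy is exact to the bit, not merely to tolerance).

Both paths evaluate the same sums the per-pixel reference loops would;
vectorization only reorders floating-point summation. The windowed path
iterates over search-window offsets d, computing the whole field
Z_d(x) as a Gaussian-filtered shifted squared difference; the full-image
path expands ‖u_x − u_y‖² over √G-weighted flattened patches blockwise
with the pair distances pinned to exactly zero on the diagonal. Test
oracles written as literal loops bound the deviation at 1e-10 per pixel;
observed deviations are at machine precision.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `patch_radius` r | 3 (7×7 patch) | patch used for similarity |
| `search_radius` s | 10 (21×21 window), or `"full"` | candidate window |
| `alpha` α | estimated noise σ | weight decay: raw weight exp(−Z/α²) |
| `eta` η | r/2 (0.5 for r = 0) | std of the patch-distance kernel |
| `self_weight_mode` | `as_printed` | raw center weight: exp(0)=1, or the max neighbor weight |

Patch and window sizes follow the classic NLM literature defaults; the
weight formula itself does not prescribe them. When α is not supplied it
defaults to the image's estimated noise standard deviation (median
absolute deviation of the finest-scale wavelet detail divided by 0.6745,
via `skimage.restoration.estimate_sigma`), which ties the decay scale to
the noise actually present. η = r/2 makes the distance kernel decay to
about e⁻² at the patch edge. The `as_printed` self-weight keeps exp(0)=1
at the center, exactly as the weight formula implies; `max_neighbor`
replaces it with the largest raw weight among the other window pixels,
the usual remedy for the center pixel's noise being counted as perfect
self-similarity.

### Numerical choices

- Intensities are processed on a [0, 1] scale; the native dynamic range
  Π (255 or 65535) is kept on the container for I/O and for the metric
  constants.
- Patches extending past the border are completed by reflection, which
  avoids phantom dark borders; the search window is clipped (not padded)
  at borders, so every pixel still lies in its own window and
  normalization is always well defined.
- The patch kernel G_η is normalized to sum 1 over the patch, making Z
  comparable across patch sizes.
- The output is a convex combination of input values; it is clipped to
  the input range only to absorb float round-off.
- Denoising is fully deterministic; all randomness lives in the phantom
  generator.

## Quality indices

All three indices are computed on the native gray scale so the
Π-dependent constants behave as written.

- **SNR** = 10·log₁₀[Σ(f² + g²) / Σ(f − g)²] dB. Base-10 logarithm (the
  decibel convention). Identical images give the +∞ sentinel.
- **SSIM** is the single global statistic
  (2f̄ḡ + a1)(2η_fg + a2) / ((f̄² + ḡ² + a1)(η_f² + η_g² + a2)) with
  a1 = 0.013Π and a2 = 0.025Π used additively exactly as given (not the
  squared (KΠ)² constants of the windowed convention, and no local
  window map). An `as_printed` dialect with the product form f̄²·ḡ² in
  the luminance denominator is preserved behind a flag for
  comparability; it is not the default because it violates the identity
  axiom SSIM(f, f) = 1 — a similarity index without that property is
  not interpretable as one, so the sum form is treated as the intended
  reading.
- **FOM** (Pratt) = [1/max(m_f, m_g)] Σ_i 1/(1 + c·l_i²), summed over
  the *test* image's edge pixels, with l_i the exact Euclidean distance
  (distance transform) to the nearest reference edge pixel and
  c = 1/9, Pratt's standard constant. The edge detector is Sobel
  gradient magnitude thresholded at a configurable fraction (default
  0.5) of its maximum — deterministic and tuning-free; detector and
  threshold are recorded in each report's `dialect_flags`.

Which image plays the reference f is genuinely ambiguous for a denoising
benchmark: scoring against the *noisy* input follows the definitions as
written, but makes a perfect denoiser score poorly. The harness therefore
computes every metric twice — reference = noisy and reference = clean —
and labels both; the clean-referenced variant is the scientifically
meaningful one and is what the efficacy checks use.

## BayesShrink comparator

Orthogonal wavelet decomposition (db4, symmetric extension, 4 levels or
the deepest the image admits — common BayesShrink practice; nothing in
the comparison pins them), noise σ̂ = median(|HH₁|)/0.6745 estimated once
from the finest diagonal subband, then each detail subband soft-
thresholded at T = σ̂²/σ_x with σ_x = √max(σ_y² − σ̂², 0); a subband whose
energy does not exceed the noise floor is zeroed (KILL). The
approximation band is untouched and the reconstruction clipped to [0, 1].
No cycle-spinning and no other shrinkage rules.

## Phantom and noise model

The synthetic phantom emulates a cardiac short-axis view: a dark
elliptical blood pool (level 0.08), a bright myocardial ring (0.85,
10 px thick) and a mid-gray background (0.35) carrying smooth seeded
texture (amplitude 0.05, correlation length ~6 px) — chosen so that both
edge preservation (ring boundaries) and smoothing (flat regions) are
exercised at ultrasound-like contrast. Speckle is modeled as
out = clip(in + √in · n, 0, 1) with n ~ N(0, σ²), the standard
signal-dependent test model for despeckling evaluation (σ defaults to
0.1); plain additive Gaussian noise is available as the second model.
Noise is applied on the [0, 1] scale and quantized only at file-write
time.

What the phantom does *not* emulate: the physics of ultrasound formation
(point-spread function, log compression, Rayleigh-distributed envelope
statistics, attenuation, sector geometry) and temporal cine structure.
Passing benchmarks therefore demonstrate correct algorithm behaviour on
speckle-like signal-dependent noise over ultrasound-like geometry, not
clinical image quality on real transesophageal frames.

## Benchmark harness

Each realization i (seed = base_seed + i) corrupts the same clean
phantom and hands the *identical* noisy image to every configured
algorithm, so comparisons are paired. Defaults: 128×128 phantom, speckle
σ = 0.1, 20 realizations, algorithms {identity, nlm, onlm, bayesshrink};
the identity no-op provides the efficacy baseline and is excluded from
significance tests. Per metric and reference the harness reports group
means/SDs, a classical one-way ANOVA F and p across the denoisers
(Welch's correction behind a flag), and a pairwise comparison table.
Degenerate cases are flagged instead of forced: a single group skips the
test, zero within-group variance is reported as such rather than as a
p-value, and groups containing non-finite values (e.g. infinite SNR of
the identity against its own input) are skipped.

The problem sizes above (128×128, 20 realizations, one noise level) are
the package's default study conditions; they are large enough for stable
group means yet small enough that the whole comparison runs in minutes
on a laptop core.

## Known limitations

- The windowed filter's cost grows with s²; the full filter is
  quadratic in pixel count and intended for small images or patience.
- Global SSIM is a blunt instrument on images with spatially varying
  degradation; that is what its definition prescribes here.
- The FOM depends on the edge detector and threshold; values are
  comparable only at fixed detector settings (hence the recorded flags).
- BayesShrink settings are conventions, not fits; comparison outcomes
  against the NLM variants depend on them.
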