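# echodenoise

Speckle denoising for echocardiographic images: a windowed non-local-means
filter (ONLM) with a classic whole-image NLM and a BayesShrink wavelet
comparator, the SNR / global-SSIM / Pratt-FOM quality indices, a synthetic
short-axis phantom generator, and a seeded benchmark harness for paired
three-algorithm comparisons with one-way ANOVA.

Ultrasound images carry speckle — granular, signal-dependent interference
that obscures myocardial borders. Non-local means suppresses it by
replacing each pixel with a weighted average of pixels whose surrounding
patches look alike:

    p*(x) = Σ_y φ(x, y) p(y),    φ(x, y) = exp(−Z(V_x, V_y)/α²) / A(x),

where Z is the Gaussian-weighted squared distance between the (2r+1)×(2r+1)
patches around x and y, α controls the weight decay and A(x) normalizes
the weights to sum to one. The windowed variant restricts the candidate
set y from the whole image to a (2s+1)×(2s+1) search window centered on x,
which preserves the behaviour while cutting the quadratic pixel-pair cost;
with a window at least the image extent it degenerates — exactly — to the
classic filter. Quality is scored by SNR = 10·log₁₀[Σ(f²+g²)/Σ(f−g)²],
a single global SSIM with constants a1 = 0.013Π and a2 = 0.025Π (Π the
native gray range), and Pratt's figure of merit over Sobel edge maps.
See `docs/methods.md` for the full model description and every default.

No real ultrasound data is required: the phantom module renders a cardiac
short-axis-like scene (dark blood-pool ellipse, bright myocardial ring,
textured background) and corrupts it with seeded signal-dependent speckle.

## Worked example

```python
from echodenoise import (PhantomSpec, NoiseSpec, make_phantom, add_noise,
                         NLMParams, nlm_denoise, metric_report)

clean = make_phantom(PhantomSpec(seed=0))                     # 128x128 phantom
noisy = add_noise(clean, NoiseSpec(sigma=0.1, seed=1))        # speckle
denoised = nlm_denoise(noisy, NLMParams(patch_radius=3, search_radius=10))

for name, ref in [("noisy input", noisy), ("clean phantom", clean)]:
    rep = metric_report(ref, denoised)
    print(f"vs {name:13s}  SNR = {rep.snr_db:.2f} dB   "
          f"SSIM = {rep.ssim:.4f}   FOM = {rep.fom:.4f}")
```

prints

```
vs noisy input    SNR = 22.58 dB   SSIM = 0.9744   FOM = 0.9990
vs clean phantom  SNR = 26.54 dB   SSIM = 0.9894   FOM = 0.8832
```

Read against the no-op baseline (noisy vs clean: 19.98 dB, SSIM 0.9532,
FOM 0.8813): the filter recovered about 6.6 dB of clean-referenced SNR and
moved SSIM from 0.953 to 0.989 while holding edge fidelity (FOM) steady —
smoothing without eroding the myocardial border. The first row scores the
output against the noisy input itself, the convention in which the metric
definitions are written; the clean-referenced row is the meaningful
measure of denoising quality, which is why the benchmark reports both.

The same operations are available from a shell:

```sh
echodenoise phantom clean.png noisy.png --sigma 0.1 --seed 1
echodenoise denoise noisy.png out.png --method onlm
echodenoise metrics clean.png out.png
echodenoise bench --out bench_results/ --n-realizations 20
```

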