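"""Benchmark harness: the three-algorithm denoising comparison.

For each noise level and realization the harness renders the clean
phantom, corrupts it with seeded noise, hands the *identical* noisy image
to every configured denoiser (so comparisons are paired), and scores each
output twice: against the noisy input (f = noisy, g = denoised — the
printed convention of the SNR/SSIM/FOM definitions) and against the clean
phantom (reference = clean, the variant under which perfect denoising
scores perfectly).  Per-condition means and standard deviations, a
one-way ANOVA across algorithms per metric, and a pairwise comparison
table are aggregated into a reproducible report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_shrink import WaveletConfig, bayes_shrink_denoise
from .image import GrayImage
from .metrics import metric_report
from .nlm import FULL, NLMParams, nlm_denoise
from .phantom import NoiseSpec, PhantomSpec, add_noise, make_phantom

__all__ = ["BenchConfig", "BenchReport", "run_benchmark", "run_denoiser", "write_report"]

logger = logging.getLogger(__name__)

_METRICS = ("snr_db", "ssim", "fom")


@dataclass(frozen=True)
class BenchConfig:
    """Declarative benchmark description; base_seed pins every random draw.

    ``algorithms`` may contain "nlm" (classic, whole-image search), "onlm"
    (windowed search), "bayesshrink" and "identity" (no-op baseline,
    excluded from the significance tests).  Realization i uses noise seed
    ``base_seed + i``; the phantom texture seed comes from
    ``phantom_spec.seed``.
    """

    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    noise_model: str = "multiplicative_speckle"
    sigmas: tuple[float, ...] = (0.1,)
    n_realizations: int = 20
    algorithms: tuple[str, ...] = ("identity", "nlm", "onlm", "bayesshrink")
    nlm_params: NLMParams = field(default_factory=lambda: NLMParams(search_radius=FULL))
    onlm_params: NLMParams = field(default_factory=NLMParams)
    wavelet_config: WaveletConfig = field(default_factory=WaveletConfig)
    base_seed: int = 0
    welch: bool = False

    def __post_init__(self) -> None:
        known = {"identity", "nlm", "onlm", "bayesshrink"}
        unknown = set(self.algorithms) - known
        if unknown:
            raise ValueError(f"unknown algorithm(s) {sorted(unknown)}; choose from {sorted(known)}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        compared = [a for a in self.algorithms if a != "identity"]
        if len(compared) >= 2 and self.n_realizations < 2:
            raise ValueError("significance testing needs n_realizations >= 2")


@dataclass(frozen=True)
class BenchReport:
    """Per-realization metric rows plus aggregate summary.

    ``rows`` has one record per (algorithm, sigma, seed, reference) with
    the metric triplet; ``summary`` nests per-condition means/stds, the
    ANOVA across algorithms, and the pairwise table.
    """

    rows: pd.DataFrame
    summary: dict
    config: BenchConfig


def run_denoiser(name: str, image: GrayImage, config: BenchConfig) -> GrayImage:
    """Run one named denoiser with the parameters from the config."""
    if name == "identity":
        return image
    if name == "nlm":
        return nlm_denoise(image, config.nlm_params)
    if name == "onlm":
        return nlm_denoise(image, config.onlm_params)
    if name == "bayesshrink":
        return bayes_shrink_denoise(image, config.wavelet_config)
    raise ValueError(f"unknown algorithm {name!r}")


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way F-test; returns (F, p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        return math.nan, math.nan
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    F = A / B
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(stats.f.sf(F, k - 1, df2))
    return float(F), p


def _anova(groups: dict[str, np.ndarray], welch: bool) -> dict:
    """One-way ANOVA across algorithm groups with degenerate-case handling."""
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        return {"note": "single group; ANOVA skipped"}
    if any(not np.all(np.isfinite(a)) for a in arrays):
        return {"note": "non-finite metric values; ANOVA skipped"}
    if all(a.var(ddof=0) == 0.0 for a in arrays):
        return {"degenerate_variance": True, "note": "zero within-group variance"}
    if welch:
        F, p = _welch_anova(arrays)
        method = "welch"
    else:
        F, p = stats.f_oneway(*arrays)
        method = "classic"
    return {"F": float(F), "p": float(p), "method": method, "groups": names}


def run_benchmark(config: BenchConfig | None = None) -> BenchReport:
    """Execute the full comparison described by the config.

    Deterministic: the same config (including ``base_seed``) reproduces
    the report bit for bit.
    """
    if config is None:
        config = BenchConfig()
    clean = make_phantom(config.phantom_spec)
    records = []
    for sigma in config.sigmas:
        for i in range(config.n_realizations):
            seed = config.base_seed + i
            noisy = add_noise(
                clean, NoiseSpec(model=config.noise_model, sigma=sigma, seed=seed)
            )
            for alg in config.algorithms:
                denoised = run_denoiser(alg, noisy, config)
                for ref_name, ref_img in (("noisy", noisy), ("clean", clean)):
                    rep = metric_report(ref_img, denoised)
                    records.append(
                        {
                            "algorithm": alg,
                            "sigma": sigma,
                            "seed": seed,
                            "reference": ref_name,
                            "snr_db": rep.snr_db,
                            "ssim": rep.ssim,
                            "fom": rep.fom,
                        }
                    )
            logger.info("sigma=%g realization %d/%d done", sigma, i + 1, config.n_realizations)
    rows = pd.DataFrame.from_records(records)

    summary: dict = {"conditions": [], "anova": [], "pairwise": []}
    compared = [a for a in config.algorithms if a != "identity"]
    for sigma in config.sigmas:
        for ref_name in ("noisy", "clean"):
            sub = rows[(rows["sigma"] == sigma) & (rows["reference"] == ref_name)]
            for alg in config.algorithms:
                vals = sub[sub["algorithm"] == alg]
                entry = {"algorithm": alg, "sigma": sigma, "reference": ref_name}
                for metric in _METRICS:
                    v = vals[metric].to_numpy(dtype=float)
                    entry[f"{metric}_mean"] = float(np.mean(v))
                    if len(v) < 2:
                        entry[f"{metric}_std"] = 0.0
                    elif np.all(np.isfinite(v)):
                        entry[f"{metric}_std"] = float(np.std(v, ddof=1))
                    else:
                        entry[f"{metric}_std"] = math.nan
                summary["conditions"].append(entry)
            for metric in _METRICS:
                groups = {
                    alg: sub[sub["algorithm"] == alg][metric].to_numpy(dtype=float)
                    for alg in compared
                }
                res = _anova(groups, config.welch)
                res.update({"sigma": sigma, "reference": ref_name, "metric": metric})
                summary["anova"].append(res)
                for a, b in combinations(compared, 2):
                    pres = _anova({a: groups[a], b: groups[b]}, config.welch)
                    pres.update(
                        {"sigma": sigma, "reference": ref_name, "metric": metric, "pair": [a, b]}
                    )
                    summary["pairwise"].append(pres)
    return BenchReport(rows=rows, summary=summary, config=config)


def _jsonable(obj):
    """Recursively convert to JSON-safe types; non-finite floats become strings."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
        return int(obj) if isinstance(obj, np.integer) else obj
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return repr(obj)


def write_report(report: BenchReport, out_dir: str | os.PathLike) -> None:
    """Write rows as CSV, summary as JSON, and echo the resolved config."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    report.rows.to_csv(os.path.join(out_dir, "bench_rows.csv"), index=False)
    with open(os.path.join(out_dir, "bench_summary.json"), "w") as fh:
        json.dump(_jsonable(report.summary), fh, indent=2)
    with open(os.path.join(out_dir, "bench_config.json"), "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(report.config)), fh, indent=2)
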