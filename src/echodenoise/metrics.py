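"""Noise-reduction quality indices: SNR, global SSIM, and Pratt's FOM.

All three are computed on the native gray scale (0..gray_range), so the
Pi-dependent SSIM constants behave as written.  SSIM here is the single
global statistic (means, variances and covariance taken over the whole
image), not a windowed map.

The SSIM luminance denominator is offered in two dialects: ``standard``
uses fbar^2 + gbar^2 (the form for which SSIM(f, f) = 1); ``as_printed``
uses the product fbar^2 * gbar^2, preserved verbatim for comparability
even though it breaks the identity axiom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.filters import sobel

from .image import GrayImage

__all__ = [
    "SSIMConstants",
    "EdgeMap",
    "MetricReport",
    "snr",
    "ssim",
    "detect_edges",
    "fom",
    "metric_report",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizing constants a1 = 0.013*Pi and a2 = 0.025*Pi.

    The constants are used additively exactly as given — they are not the
    squared (K*Pi)**2 constants of the windowed-SSIM convention.
    """

    gray_range: int = 255
    a1: float = None  # type: ignore[assignment]
    a2: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a1 is None:
            object.__setattr__(self, "a1", 0.013 * self.gray_range)
        if self.a2 is None:
            object.__setattr__(self, "a2", 0.025 * self.gray_range)


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster with its edge-pixel count."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("edge mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MetricReport:
    """SNR/SSIM/FOM triplet for one (reference, test) image pair."""

    snr_db: float
    ssim: float
    fom: float
    dialect_flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "ssim": self.ssim,
            "fom": self.fom,
            "dialect_flags": dict(self.dialect_flags),
        }


def _native_pair(f: GrayImage, g: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    if f.shape != g.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {g.shape}")
    return f.values * f.gray_range, g.values * g.gray_range


def snr(f: GrayImage, g: GrayImage) -> float:
    """Signal-to-noise ratio between two images, in decibels.

    10 * log10( sum(f^2 + g^2) / sum((f - g)^2) ) on the native gray
    scale.  Identical images give math.inf; two identically zero images
    are undefined and raise.
    """
    fa, ga = _native_pair(f, g)
    num = float((fa**2 + ga**2).sum())
    den = float(((fa - ga) ** 2).sum())
    if den == 0.0:
        if num == 0.0:
            raise ValueError("SNR undefined for two identically zero images")
        return math.inf
    return 10.0 * math.log10(num / den)


def ssim(
    f: GrayImage,
    g: GrayImage,
    constants: SSIMConstants | None = None,
    dialect: Literal["standard", "as_printed"] = "standard",
) -> float:
    """Global structural similarity between two images.

    standard:   (2 fbar gbar + a1)(2 cov + a2) /
                ((fbar^2 + gbar^2 + a1)(var_f + var_g + a2))
    as_printed: the luminance denominator uses fbar^2 * gbar^2 instead.
    """
    if constants is None:
        constants = SSIMConstants(gray_range=f.gray_range)
    fa, ga = _native_pair(f, g)
    fbar, gbar = fa.mean(), ga.mean()
    var_f = fa.var()
    var_g = ga.var()
    cov = ((fa - fbar) * (ga - gbar)).mean()
    a1, a2 = constants.a1, constants.a2
    num = (2.0 * fbar * gbar + a1) * (2.0 * cov + a2)
    if dialect == "standard":
        lum_den = fbar**2 + gbar**2 + a1
    elif dialect == "as_printed":
        lum_den = fbar**2 * gbar**2 + a1
    else:
        raise ValueError(f"unknown SSIM dialect {dialect!r}")
    return float(num / (lum_den * (var_f + var_g + a2)))


def detect_edges(image: GrayImage, threshold_fraction: float = 0.5) -> EdgeMap:
    """Binary edge map: Sobel gradient magnitude thresholded at a fraction
    of its maximum.

    Deterministic and tuning-free; a constant image has no edges.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    mag = sobel(image.values)
    peak = mag.max()
    if peak == 0.0:
        return EdgeMap(np.zeros(image.shape, dtype=bool))
    return EdgeMap(mag >= threshold_fraction * peak)


def fom(reference_edges: EdgeMap, test_edges: EdgeMap, c: float = 1.0 / 9.0) -> float:
    """Pratt's figure of merit for edge preservation.

    FOM = (1 / max(m_ref, m_test)) * sum_i 1 / (1 + c * l_i^2), summing
    over the test edge pixels, with l_i the Euclidean distance from test
    edge pixel i to the nearest reference edge pixel.  1 means every test
    edge pixel sits on a reference edge pixel and counts agree.
    """
    if c <= 0:
        raise ValueError("FOM constant c must be positive")
    m_ref, m_test = reference_edges.count, test_edges.count
    if m_ref == 0 or m_test == 0:
        raise ValueError("FOM undefined for an empty edge map")
    if reference_edges.mask.shape != test_edges.mask.shape:
        raise ValueError("edge maps must share a shape")
    dist = distance_transform_edt(~reference_edges.mask)
    l = dist[test_edges.mask]
    return float(np.sum(1.0 / (1.0 + c * l**2)) / max(m_ref, m_test))


def metric_report(
    f: GrayImage,
    g: GrayImage,
    ssim_dialect: Literal["standard", "as_printed"] = "standard",
    edge_threshold_fraction: float = 0.5,
    fom_c: float = 1.0 / 9.0,
) -> MetricReport:
    """Compute the SNR/SSIM/FOM triplet for a (reference f, test g) pair.

    FOM uses the Sobel edge maps of both images; when either map is empty
    (e.g. a constant reference), FOM is reported as NaN rather than
    raising.
    """
    ef = detect_edges(f, edge_threshold_fraction)
    eg = detect_edges(g, edge_threshold_fraction)
    if ef.count == 0 or eg.count == 0:
        fom_val = math.nan
    else:
        fom_val = fom(ef, eg, c=fom_c)
    return MetricReport(
        snr_db=snr(f, g),
        ssim=ssim(f, g, dialect=ssim_dialect),
        fom=fom_val,
        dialect_flags={
            "ssim_dialect": ssim_dialect,
            "edge_detector": "sobel",
            "edge_threshold_fraction": edge_threshold_fraction,
            "fom_c": fom_c,
        },
    )
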