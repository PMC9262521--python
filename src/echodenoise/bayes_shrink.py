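"""BayesShrink adaptive wavelet soft-thresholding (comparator denoiser).

Each detail subband of an orthogonal wavelet decomposition is soft-
thresholded at T = sigma_n^2 / sigma_x, where sigma_n is the noise
standard deviation (estimated robustly from the finest diagonal subband)
and sigma_x = sqrt(max(sigma_y^2 - sigma_n^2, 0)) the estimated signal
standard deviation of the subband; a subband whose energy does not exceed
the noise floor is zeroed entirely.  The approximation band is left
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

from .image import GrayImage

__all__ = [
    "KILL",
    "WaveletConfig",
    "estimate_noise_sigma",
    "subband_threshold",
    "bayes_shrink_denoise",
]

#: Sentinel threshold meaning "zero the whole subband" (pure-noise subband).
KILL = math.inf


@dataclass(frozen=True)
class WaveletConfig:
    """Decomposition settings: wavelet family, depth, boundary extension."""

    family: str = "db4"
    levels: int = 4
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def estimate_noise_sigma(finest_diagonal_subband: np.ndarray) -> float:
    """Robust noise-sigma estimate: median(|coefficients|) / 0.6745."""
    c = np.asarray(finest_diagonal_subband, dtype=np.float64)
    if c.size == 0:
        raise ValueError("cannot estimate noise from an empty subband")
    return float(np.median(np.abs(c)) / 0.6745)


def subband_threshold(sigma_hat: float, subband: np.ndarray) -> float:
    """BayesShrink threshold for one detail subband.

    Returns sigma_hat**2 / sigma_x with sigma_x the subband's estimated
    signal std; returns the KILL sentinel (inf) when the subband carries
    no signal energy above the noise floor.
    """
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be nonnegative")
    c = np.asarray(subband, dtype=np.float64)
    if c.size == 0:
        raise ValueError("empty subband")
    sigma_y2 = float(np.mean(c**2))
    sigma_x = math.sqrt(max(sigma_y2 - sigma_hat**2, 0.0))
    if sigma_x == 0.0:
        return KILL
    return sigma_hat**2 / sigma_x


def _admissible_levels(shape: tuple[int, int], config: WaveletConfig) -> int:
    wav = pywt.Wavelet(config.family)
    max_lv = min(pywt.dwt_max_level(s, wav.dec_len) for s in shape)
    return min(config.levels, max_lv)


def bayes_shrink_denoise(image: GrayImage, config: WaveletConfig | None = None) -> GrayImage:
    """Denoise by per-subband BayesShrink soft thresholding.

    The decomposition depth is capped at the deepest level the image size
    admits for the chosen wavelet; an image too small for even one level
    raises.  Output is clipped to [0, 1].
    """
    if config is None:
        config = WaveletConfig()
    levels = _admissible_levels(image.shape, config)
    if levels < 1:
        raise ValueError(
            f"image of shape {image.shape} too small for a {config.family} decomposition"
        )
    coeffs = pywt.wavedec2(image.values, config.family, mode=config.boundary_mode, level=levels)
    sigma_hat = estimate_noise_sigma(coeffs[-1][2])  # level-1 diagonal (HH)
    new_coeffs = [coeffs[0]]
    for bands in coeffs[1:]:
        shrunk = []
        for band in bands:
            t = subband_threshold(sigma_hat, band)
            if t == KILL:
                shrunk.append(np.zeros_like(band))
            else:
                shrunk.append(pywt.threshold(band, t, mode="soft"))
        new_coeffs.append(tuple(shrunk))
    rec = pywt.waverec2(new_coeffs, config.family, mode=config.boundary_mode)
    rec = rec[: image.height, : image.width]  # waverec2 may pad odd sizes by one
    return GrayImage(np.clip(rec, 0.0, 1.0), image.gray_range)
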