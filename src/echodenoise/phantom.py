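"""Synthetic short-axis echocardiography phantom and speckle-noise model.

The phantom imitates the salient structure of a cardiac short-axis view:
a dark elliptical blood-pool chamber, a bright myocardial ring around it,
and a mid-gray background carrying smooth low-frequency tissue texture.
Noise is either signal-dependent speckle — Gaussian noise scaled by the
square root of the local intensity, the standard despeckling test model —
or plain additive Gaussian.  Everything is seeded and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import GrayImage

__all__ = ["PhantomSpec", "NoiseSpec", "make_phantom", "add_noise"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity levels of the synthetic scene.

    ``chamber_radius`` is the (row, col) semi-axis pair of the blood-pool
    ellipse; the myocardial ring extends ``ring_thickness`` pixels beyond
    it.  Intensities must satisfy chamber < background < ring so the scene
    has an ultrasound-like contrast ordering.
    """

    height: int = 128
    width: int = 128
    chamber_center: tuple[float, float] = (64.0, 64.0)
    chamber_radius: tuple[float, float] = (22.0, 28.0)
    ring_thickness: float = 10.0
    background_level: float = 0.35
    ring_level: float = 0.85
    chamber_level: float = 0.08
    texture_amplitude: float = 0.05
    texture_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must be at least 1x1")
        if not 0.0 <= self.chamber_level < self.background_level < self.ring_level <= 1.0:
            raise ValueError("need 0 <= chamber_level < background_level < ring_level <= 1")
        cy, cx = self.chamber_center
        ry, rx = self.chamber_radius
        t = self.ring_thickness
        if ry <= 0 or rx <= 0 or t < 0:
            raise ValueError("radii must be positive, ring_thickness nonnegative")
        if (
            cy - (ry + t) < 0
            or cy + (ry + t) > self.height - 1
            or cx - (rx + t) < 0
            or cx + (rx + t) > self.width - 1
        ):
            raise ValueError("chamber plus ring must fit inside the image")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and scale.

    multiplicative_speckle: out = in + sqrt(in) * n,  n ~ N(0, sigma^2)
    additive_gaussian:      out = in + n
    both clipped to [0, 1].
    """

    model: Literal["multiplicative_speckle", "additive_gaussian"] = "multiplicative_speckle"
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.model not in ("multiplicative_speckle", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")


def make_phantom(spec: PhantomSpec | None = None) -> GrayImage:
    """Render the piecewise scene plus seeded smooth texture.

    With ``texture_amplitude`` 0 the image takes exactly the three level
    values.  The texture is white noise smoothed to ``texture_scale``
    pixels and rescaled to peak amplitude ``texture_amplitude``, so it
    perturbs all regions without reordering their means.
    """
    if spec is None:
        spec = PhantomSpec()
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    cy, cx = spec.chamber_center
    ry, rx = spec.chamber_radius
    rho_inner = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    rho_outer = ((yy - cy) / (ry + spec.ring_thickness)) ** 2 + (
        (xx - cx) / (rx + spec.ring_thickness)
    ) ** 2
    img = np.full((spec.height, spec.width), spec.background_level)
    img[rho_outer <= 1.0] = spec.ring_level
    img[rho_inner <= 1.0] = spec.chamber_level
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        tex = gaussian_filter(rng.standard_normal((spec.height, spec.width)), spec.texture_scale)
        peak = np.abs(tex).max()
        if peak > 0:
            img = img + tex * (spec.texture_amplitude / peak)
    return GrayImage(np.clip(img, 0.0, 1.0))


def add_noise(image: GrayImage, noise: NoiseSpec | None = None) -> GrayImage:
    """Corrupt an image with seeded speckle or Gaussian noise."""
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    n = rng.standard_normal(image.shape) * noise.sigma
    if noise.model == "multiplicative_speckle":
        out = image.values + np.sqrt(image.values) * n
    else:
        out = image.values + n
    return GrayImage(np.clip(out, 0.0, 1.0), image.gray_range)
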