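"""Grayscale image container and single-channel PNG/TIFF I/O.

All processing in this package happens on intensities normalized to [0, 1];
the native dynamic range ``gray_range`` (255 for 8-bit, 65535 for 16-bit)
is carried along because the quality metrics are defined on the native
gray scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image as _PILImage

__all__ = ["GrayImage", "read_image", "write_image", "ImageFormatError"]


class ImageFormatError(ValueError):
    """Raised for unsupported image files (multi-channel, odd bit depth)."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with values normalized to [0, 1].

    Parameters
    ----------
    values : ndarray, shape (H, W)
        Float intensities in [0, 1].
    gray_range : int
        Native dynamic range Pi of the encoding (255 for 8-bit images,
        65535 for 16-bit). Used by the SSIM stabilizing constants and for
        quantization on write.
    """

    values: np.ndarray
    gray_range: int = 255

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("GrayImage values must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("GrayImage values must lie in [0, 1]")
        if self.gray_range <= 0:
            raise ValueError("gray_range must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_native(cls, arr: np.ndarray, gray_range: int | None = None) -> "GrayImage":
        """Build from a raster on its native integer scale.

        ``gray_range`` is inferred from the dtype (uint8 -> 255,
        uint16 -> 65535) when not given.
        """
        arr = np.asarray(arr)
        if gray_range is None:
            if arr.dtype == np.uint8:
                gray_range = 255
            elif arr.dtype == np.uint16:
                gray_range = 65535
            else:
                raise ImageFormatError(
                    f"cannot infer gray range from dtype {arr.dtype}; pass gray_range"
                )
        return cls(arr.astype(np.float64) / gray_range, gray_range)

    def to_native(self) -> np.ndarray:
        """Quantize to the native integer scale (round-half-even)."""
        q = np.rint(self.values * self.gray_range)
        dtype = np.uint8 if self.gray_range <= 255 else np.uint16
        return q.astype(dtype)


def _check_single_channel(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 3:
        raise ImageFormatError(
            f"{path}: expected a single-channel image, got shape {arr.shape}; "
            "convert to grayscale explicitly before denoising"
        )
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    return arr


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read an 8- or 16-bit single-channel PNG or TIFF.

    Multi-channel files are rejected rather than silently converted.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".png":
        with _PILImage.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P", "LA"):
                raise ImageFormatError(
                    f"{path}: expected a single-channel image, got mode {im.mode!r}; "
                    "convert to grayscale explicitly before denoising"
                )
            arr = np.asarray(im)
            if im.mode in ("I;16", "I"):
                arr = arr.astype(np.uint16)
    else:
        raise ImageFormatError(f"{path}: unsupported extension {ext!r} (use .png/.tif/.tiff)")
    arr = _check_single_channel(np.asarray(arr), path)
    if arr.dtype == np.uint8:
        return GrayImage.from_native(arr, 255)
    if arr.dtype == np.uint16:
        return GrayImage.from_native(arr, 65535)
    raise ImageFormatError(f"{path}: unsupported bit depth {arr.dtype} (use uint8 or uint16)")


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write as 8- or 16-bit single-channel PNG/TIFF, per ``gray_range``."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    native = image.to_native()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, native)
    elif ext == ".png":
        if native.dtype == np.uint16:
            _PILImage.fromarray(native).save(path)
        else:
            _PILImage.fromarray(native, mode="L").save(path)
    else:
        raise ImageFormatError(f"{path}: unsupported extension {ext!r} (use .png/.tif/.tiff)")
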