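"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal per-pixel / per-offset loops, kept
deliberately separate from the vectorized package code it checks.
"""

from __future__ import annotations

import numpy as np


def brute_patch_kernel(r: int, eta: float) -> np.ndarray:
    kern = np.empty((2 * r + 1, 2 * r + 1))
    for i, ky in enumerate(range(-r, r + 1)):
        for j, kx in enumerate(range(-r, r + 1)):
            kern[i, j] = np.exp(-(ky * ky + kx * kx) / (2.0 * eta * eta))
    return kern / kern.sum()


def brute_patch_distance(img: np.ndarray, x, y, r: int, eta: float) -> float:
    """Double loop over patch offsets on a reflect-padded image."""
    P = np.pad(img, r, mode="reflect") if r > 0 else img
    kern = brute_patch_kernel(r, eta)
    z = 0.0
    for i, ky in enumerate(range(-r, r + 1)):
        for j, kx in enumerate(range(-r, r + 1)):
            a = P[x[0] + ky + r, x[1] + kx + r]
            b = P[y[0] + ky + r, y[1] + kx + r]
            z += kern[i, j] * (a - b) ** 2
    return z


def brute_window(shape, x, search_radius):
    """Search window coordinates: whole image or clipped square around x."""
    H, W = shape
    if search_radius == "full":
        return [(a, b) for a in range(H) for b in range(W)]
    s = search_radius
    return [
        (a, b)
        for a in range(max(0, x[0] - s), min(H, x[0] + s + 1))
        for b in range(max(0, x[1] - s), min(W, x[1] + s + 1))
    ]


def brute_weights(img, x, r, search_radius, alpha, eta, self_weight_mode="as_printed"):
    """Raw exp(-Z/alpha^2) weights over the window, then normalized."""
    coords = brute_window(img.shape, x, search_radius)
    raw = np.array(
        [np.exp(-brute_patch_distance(img, x, y, r, eta) / alpha**2) for y in coords]
    )
    if self_weight_mode == "max_neighbor" and len(raw) > 1:
        ci = coords.index((x[0], x[1]))
        raw[ci] = np.delete(raw, ci).max()
    return coords, raw / raw.sum()


def brute_nlm(img, r, search_radius, alpha, eta, self_weight_mode="as_printed"):
    """Literal weighted-average filter: loops over pixels and window."""
    H, W = img.shape
    out = np.zeros((H, W))
    for x0 in range(H):
        for x1 in range(W):
            coords, w = brute_weights(
                img, (x0, x1), r, search_radius, alpha, eta, self_weight_mode
            )
            out[x0, x1] = sum(wi * img[a, b] for wi, (a, b) in zip(w, coords))
    return out


def brute_window_mean(img, x, search_radius):
    """Unweighted mean of the clipped search window (alpha -> inf limit)."""
    coords = brute_window(img.shape, x, search_radius)
    return float(np.mean([img[a, b] for a, b in coords]))
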