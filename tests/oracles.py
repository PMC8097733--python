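"""Independent brute-force reference implementations used only by tests.

Deliberately naive: direct dense convolution, double-loop morphology, and
explicit histogram walks.  They share no code with the package so they can
serve as oracles for it.
"""

import numpy as np


def direct_gaussian_blur(plane: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Dense 2-D convolution with an explicitly constructed truncated
    Gaussian kernel; edge-replicated boundaries."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    padded = np.pad(plane, radius, mode="edge")
    h, w = plane.shape
    out = np.zeros_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel)
    return out


def ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element: hemisphere of XY radius ``radius``."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (xx * xx + yy * yy).astype(float)
    footprint = d2 <= radius * radius
    heights = np.where(footprint, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return footprint, heights


def direct_grey_opening(plane: np.ndarray, radius: float) -> np.ndarray:
    """Erosion then dilation with the ball element, written as explicit
    double loops over structuring-element offsets; edge-replicated."""
    footprint, heights = ball_element(radius)
    r = footprint.shape[0] // 2
    offsets = [
        (dy - r, dx - r, heights[dy, dx])
        for dy in range(footprint.shape[0])
        for dx in range(footprint.shape[1])
        if footprint[dy, dx]
    ]
    h, w = plane.shape

    def pad_at(arr, i, j):
        return arr[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]

    eroded = np.empty_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            eroded[i, j] = min(pad_at(plane, i + dy, j + dx) - hh for dy, dx, hh in offsets)
    opened = np.empty_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            opened[i, j] = max(pad_at(eroded, i - dy, j - dx) + hh for dy, dx, hh in offsets)
    return opened


def percentile_bounds(values: np.ndarray, saturated_percent: float) -> tuple[float, float]:
    """Display bounds from the sorted values: at most ``saturated_percent/2``
    percent of pixels strictly below/above the bounds, on a 256-bin histogram
    of the range."""
    flat = np.sort(values.ravel())
    lo, hi = flat[0], flat[-1]
    if hi <= lo:
        return float(lo), float(lo + 1)
    allowance = flat.size * saturated_percent / 200.0
    edges = np.linspace(lo, hi, 257)
    counts, _ = np.histogram(flat, bins=edges)
    cum = 0
    low = lo
    for b in range(256):
        if cum + counts[b] > allowance:
            low = flat[np.searchsorted(flat, edges[b], side="left")]
            break
        cum += counts[b]
    cum = 0
    high = hi
    for b in range(255, -1, -1):
        if cum + counts[b] > allowance:
            below = np.searchsorted(flat, edges[b + 1], side="right")
            high = flat[below - 1]
            break
        cum += counts[b]
    return float(low), float(high)
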