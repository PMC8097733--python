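"""Per-plane tone-mapping operators.

The core transform homogenizes the dynamic range of a fluorescence image in
three steps: division by a Gaussian-blurred copy of the image (a pseudo
flat-field that acts as a local gain control), a square root (compresses the
remaining range non-linearly), and a rolling-ball background subtraction
(removes the smooth pedestal the division leaves behind).  A single parameter
``p`` — the pixel size of the largest object of interest — drives everything:
the blur sigma defaults to ``2*p`` and the rolling-ball radius to ``p``.

Alongside the main transform this module provides the classical display
operators it is usually compared against: linear min-max mapping,
percentile-based auto-contrast, gamma correction, plain square root, and
background subtraction on its own.

All operators take and return 2-D float64 arrays ("planes") and never mutate
their input.  Integer conversion is deliberately a separate, final step
(:func:`convert_bit_depth`) so the float operators stay composable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage


class ParameterError(ValueError):
    """Raised when an operator parameter violates its contract."""


#: truncation of the Gaussian kernel support, in units of sigma
GAUSSIAN_TRUNCATE = 4.0

#: display scale used when ``division_scale="auto"``.  The divided image is
#: O(1) (background ~1), so this puts the square-rooted output in the
#: thousands, matching the default 16-bit conversion window (-100, 10000).
#: The rolling-ball element has fixed curvature in intensity units; at this
#: scale it is nearly flat relative to the signal, which makes the operator
#: effectively scale-homogeneous (normalized benchmark reports do not depend
#: on the choice).
DEFAULT_DIVISION_SCALE = 1.0e6


def as_plane(values) -> np.ndarray:
    """Validate and coerce ``values`` to a 2-D float64 plane.

    Raises :class:`ParameterError` on non-2D input or non-finite values.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ParameterError(f"plane must be 2-D with positive shape, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("plane contains non-finite values (NaN/Inf)")
    return arr


@dataclass(frozen=True)
class DevilsParams:
    """Parameters of the tone-mapping operator.

    Parameters
    ----------
    p:
        Size of the largest object of interest, in pixels.  The only knob a
        user normally touches.
    sigma:
        Standard deviation of the Gaussian used for the division, in pixels.
        Defaults to ``2 * p``.
    ball_radius:
        XY radius of the rolling-ball structuring element, in pixels.
        Defaults to ``p``.
    division_scale:
        Multiplier applied to the divided image before the square root, or
        ``"auto"`` for the default display scale
        (:data:`DEFAULT_DIVISION_SCALE`).  Amplification reports on the disk
        phantom are normalized and therefore independent of this choice;
        :func:`devils.phantom_bench.calibrate_scale` computes the alternative
        measurement-anchored scale if one is wanted explicitly.
    epsilon:
        Additive guard in the division.  ``None`` selects a scale-aware
        default of ``1e-6 *`` the mean of the blurred plane (or ``1e-6`` if
        that mean is zero).
    conv_min, conv_max:
        Bounds used when converting the float result to 8- or 16-bit.
    out_depth:
        Output bit depth, one of 8, 16 (integer conversion) or 32 (identity).
    """

    p: float
    sigma: float | None = None
    ball_radius: float | None = None
    division_scale: Union[float, str] = "auto"
    epsilon: float | None = None
    conv_min: float = -100.0
    conv_max: float = 10000.0
    out_depth: int = 16

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ParameterError(f"p must be > 0, got {self.p}")
        if self.sigma is not None and not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.ball_radius is not None and not self.ball_radius >= 1:
            raise ParameterError(f"ball_radius must be >= 1, got {self.ball_radius}")
        if isinstance(self.division_scale, str):
            if self.division_scale != "auto":
                raise ParameterError(f"division_scale must be numeric or 'auto', got {self.division_scale!r}")
        elif not self.division_scale > 0:
            raise ParameterError(f"division_scale must be > 0, got {self.division_scale}")
        if self.epsilon is not None and not self.epsilon > 0:
            raise ParameterError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.conv_max > self.conv_min:
            raise ParameterError(f"conv_max ({self.conv_max}) must exceed conv_min ({self.conv_min})")
        if self.out_depth not in (8, 16, 32):
            raise ParameterError(f"out_depth must be 8, 16 or 32, got {self.out_depth}")

    @property
    def resolved_sigma(self) -> float:
        return float(self.sigma) if self.sigma is not None else 2.0 * self.p

    @property
    def resolved_ball_radius(self) -> float:
        return float(self.ball_radius) if self.ball_radius is not None else float(self.p)


def gaussian_blur(plane, sigma: float) -> np.ndarray:
    """Convolve with a normalized 2-D Gaussian (std ``sigma`` px).

    Boundaries are handled by edge replication; the kernel support is
    truncated at ``4*sigma``.
    """
    arr = as_plane(plane)
    if not sigma > 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest", truncate=GAUSSIAN_TRUNCATE)


def _resolve_epsilon(blurred: np.ndarray, epsilon: float | None) -> float:
    if epsilon is not None:
        return float(epsilon)
    m = float(blurred.mean())
    return 1e-6 * (m if m > 0 else 1.0)


def divide_by_blur(plane, sigma: float, scale: float = 1.0, epsilon: float | None = None) -> np.ndarray:
    """Pseudo flat-field division: ``scale * I / (G + epsilon)``.

    ``G`` is the plane blurred with ``sigma``; ``epsilon`` guards against
    division by zero (see :class:`DevilsParams` for the default).
    """
    arr = as_plane(plane)
    if not scale > 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    blurred = gaussian_blur(arr, sigma)
    eps = _resolve_epsilon(blurred, epsilon)
    return scale * arr / (blurred + eps)


def sqrt_transform(plane) -> np.ndarray:
    """Pixelwise square root; negatives are clamped to 0 first.

    Inputs are nonnegative by contract, but float round-off after the
    division step can produce tiny negatives.
    """
    arr = as_plane(plane)
    return np.sqrt(np.maximum(arr, 0.0))


def gamma_transform(plane, gamma: float, display_max: float) -> np.ndarray:
    """Gamma display mapping: ``((I/display_max)**gamma) * display_max``.

    Input is clamped to ``[0, display_max]`` first.  ``gamma=0.5`` with
    ``display_max = I.max()`` is the square root up to the ``sqrt(display_max)``
    normalization factor.
    """
    arr = as_plane(plane)
    if not gamma > 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    if not display_max > 0:
        raise ParameterError(f"display_max must be > 0, got {display_max}")
    clamped = np.clip(arr, 0.0, display_max)
    return (clamped / display_max) ** gamma * display_max


def _ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a spherical-cap structuring element.

    The cap spans XY radius ``radius`` with height profile
    ``h(d) = sqrt(R**2 - d**2)`` (a hemisphere; gray-scale opening is
    invariant to the constant offset, so this equals the usual
    ``R - sqrt(R**2 - d**2)`` depth convention up to sign).
    """
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (xx * xx + yy * yy).astype(np.float64)
    footprint = d2 <= radius * radius
    heights = np.where(footprint, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return footprint, heights


def rolling_ball_background(plane, radius: float) -> np.ndarray:
    """Background estimate by exact gray-scale opening with a ball element.

    Erosion by the spherical cap followed by dilation: the surface traced by
    a ball of XY radius ``radius`` rolled under the intensity landscape.
    Guaranteed ``background <= plane`` pointwise.  This is the exact opening,
    without the shrink/interpolate speed-up some implementations use, so it
    can be checked against a brute-force oracle.
    """
    arr = as_plane(plane)
    if not radius >= 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    footprint, heights = _ball_element(radius)
    eroded = ndimage.grey_erosion(arr, footprint=footprint, structure=heights, mode="nearest")
    return ndimage.grey_dilation(eroded, footprint=footprint, structure=heights, mode="nearest")


def subtract_background(plane, radius: float) -> np.ndarray:
    """Subtract the rolling-ball background estimate from the plane."""
    arr = as_plane(plane)
    return arr - rolling_ball_background(arr, radius)


def devils_transform(plane, params: DevilsParams) -> np.ndarray:
    """The full tone-mapping operator.

    ``subtract_background(sqrt(scale * I / (blur(I, sigma) + eps)), ball_radius)``
    with defaults ``sigma = 2p`` and ``ball_radius = p``.  The output is
    real-valued and unconverted; apply :func:`convert_bit_depth` at write
    time.  A ``division_scale`` of ``"auto"`` resolves to
    :data:`DEFAULT_DIVISION_SCALE`.
    """
    arr = as_plane(plane)
    scale = resolve_division_scale(params)
    divided = divide_by_blur(arr, params.resolved_sigma, scale, params.epsilon)
    rooted = sqrt_transform(divided)
    return subtract_background(rooted, params.resolved_ball_radius)


def resolve_division_scale(params: DevilsParams) -> float:
    """Return the numeric division scale (``"auto"`` -> the display scale)."""
    if isinstance(params.division_scale, str):
        return DEFAULT_DIVISION_SCALE
    return float(params.division_scale)


def auto_contrast_range(plane, saturated_percent: float) -> tuple[float, float]:
    """Display bounds that saturate at most ``saturated_percent`` of pixels.

    The allowance splits equally between the two tails and is evaluated on a
    256-bin histogram of the plane's range, mirroring the usual auto-contrast
    behaviour of interactive viewers.  Degenerate (constant) planes return
    ``(min, min + 1)``.
    """
    arr = as_plane(plane)
    if not (0 <= saturated_percent < 100):
        raise ParameterError(f"saturated_percent must be in [0, 100), got {saturated_percent}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return lo, lo + 1.0
    counts, edges = np.histogram(arr, bins=256, range=(lo, hi))
    allowance = arr.size * saturated_percent / 200.0

    cum = np.cumsum(counts)
    i_low = int(np.searchsorted(cum, allowance, side="right"))
    low = float(arr[arr >= edges[i_low]].min())

    cum_top = np.cumsum(counts[::-1])
    i_top = int(np.searchsorted(cum_top, allowance, side="right"))
    high = float(arr[arr <= edges[256 - i_top]].max())

    if high <= low:
        return low, low + 1.0
    return low, high


def linear_display_map(plane, low: float, high: float) -> np.ndarray:
    """Linear min-max display mapping to [0, 1]; out-of-range values saturate."""
    arr = as_plane(plane)
    if not high > low:
        raise ParameterError(f"high ({high}) must exceed low ({low})")
    return np.clip((arr - low) / (high - low), 0.0, 1.0)


def convert_bit_depth(plane, conv_min: float, conv_max: float, out_depth: int) -> np.ndarray:
    """Convert a float plane to 8- or 16-bit with the given bounds.

    ``out = round(clip((I - conv_min) / (conv_max - conv_min), 0, 1) * (2**depth - 1))``.
    32-bit output is the identity (values pass through as float32).
    """
    arr = as_plane(plane)
    if not conv_max > conv_min:
        raise ParameterError(f"conv_max ({conv_max}) must exceed conv_min ({conv_min})")
    if out_depth == 32:
        return arr.astype(np.float32)
    if out_depth not in (8, 16):
        raise ParameterError(f"out_depth must be 8, 16 or 32, got {out_depth}")
    top = 2**out_depth - 1
    scaled = np.clip((arr - conv_min) / (conv_max - conv_min), 0.0, 1.0) * top
    dtype = np.uint8 if out_depth == 8 else np.uint16
    return np.rint(scaled).astype(dtype)
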