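"""Static-image fluorescence quantification.

Utilities for the immunostaining-style read-outs that accompany the live
imaging: background-subtracted mean reporter intensity inside a cell mask,
thresholded marker area (e.g. the ninein-positive region), and bilinear
line profiles between two points (e.g. connecting the two centrioles),
with endpoint-associated and midpoint summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "IntensityMeasure",
    "reporter_intensity",
    "area_above_threshold",
    "line_profile",
]


@dataclass
class IntensityMeasure:
    """One quantified measure with its acquisition context."""

    cell_id: int
    kind: str  # {"reporter_mean", "area_um2", "line_profile"}
    value: float | np.ndarray
    threshold: float | None = None
    background: float | None = None
    pixel_size_um: float | None = None
    label: str | None = None  # phase / orientation grouping column


def reporter_intensity(
    image: np.ndarray, cell_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Mean in-mask intensity minus mean background intensity.

    May be negative (reported as-is).
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not cell_mask.any() or not background_mask.any():
        raise ValueError("cell and background regions must be nonempty")
    return float(image[cell_mask].mean() - image[background_mask].mean())


def area_above_threshold(
    image: np.ndarray, threshold: float | str, pixel_size_um: float
) -> float:
    """Suprathreshold area in um^2 (``threshold`` may be 'otsu')."""
    image = np.asarray(image, dtype=float)
    if threshold == "otsu":
        threshold = float(threshold_otsu(image))
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return float(np.count_nonzero(image > threshold)) * pixel_size_um**2


def line_profile(
    image: np.ndarray,
    point_a: tuple[float, float],
    point_b: tuple[float, float],
    n_samples: int = 50,
    endpoint_window: int = 3,
) -> dict:
    """Bilinear intensity samples along the segment from a to b.

    Points are ``(x, y)`` pixel coordinates (pixel centres).  Returns the
    sample vector plus means over the first/last ``endpoint_window``
    samples (a-/b-associated) and the centred midpoint window.  A
    degenerate segment (a == b) yields a single-sample profile.
    """
    image = np.asarray(image, dtype=float)
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    for p in (a, b):
        if not (0 <= p[0] <= image.shape[1] - 1 and 0 <= p[1] <= image.shape[0] - 1):
            raise ValueError(f"point {tuple(p)} outside the image")
    if np.allclose(a, b):
        val = float(
            ndimage.map_coordinates(image, [[a[1]], [a[0]]], order=1, mode="nearest")[0]
        )
        return {
            "samples": np.array([val]),
            "a_mean": val,
            "mid_mean": val,
            "b_mean": val,
        }
    t = np.linspace(0.0, 1.0, n_samples)
    xs = a[0] + t * (b[0] - a[0])
    ys = a[1] + t * (b[1] - a[1])
    samples = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    w = min(endpoint_window, n_samples)
    mid = n_samples // 2
    half = max(w // 2, 1)
    lo = max(mid - half, 0)
    hi = min(lo + w, n_samples)
    return {
        "samples": samples,
        "a_mean": float(samples[:w].mean()),
        "mid_mean": float(samples[lo:hi].mean()),
        "b_mean": float(samples[-w:].mean()),
    }
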