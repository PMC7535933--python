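"""Drift correction of 3D time-lapse series and track-level detrending.

x-y drift is estimated by 2D phase correlation of maximum-intensity
projections between consecutive frames; z drift by phase correlation of
the axial (z) intensity profile.  Frame-to-frame estimates are chained
cumulatively to a chosen reference frame, which is robust to the slow
morphological changes of a developing explant.  Registration corrects
translation only; no rotation or deformation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import CentrioleTrack

__all__ = [
    "ShiftSeries",
    "estimate_shifts",
    "apply_shifts",
    "detrend_tracks",
]


@dataclass
class ShiftSeries:
    """Per-frame (dz, dy, dx) voxel shifts relative to a reference frame.

    ``shifts[t]`` is the displacement of frame ``t``'s content relative to
    the reference; applying the inverse translation realigns the series.
    The shift at the reference frame is zero by construction.
    """

    shifts: np.ndarray  # (T, 3) voxels (dz, dy, dx)
    reference: int
    scores: np.ndarray  # per-frame correlation confidence in [0, 1]
    low_confidence: np.ndarray  # per-frame flag

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.low_confidence = np.asarray(self.low_confidence, dtype=bool)
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")
        if not np.allclose(self.shifts[self.reference], 0.0):
            raise ValueError("shift at the reference frame must be zero")

    def __len__(self) -> int:
        return len(self.shifts)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "dz": self.shifts[:, 0],
                "dy": self.shifts[:, 1],
                "dx": self.shifts[:, 2],
                "score": self.scores,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_table().to_csv(path, index=False)
        return path


def _pairwise_shift(
    prev: np.ndarray, cur: np.ndarray, upsample: int
) -> tuple[np.ndarray, float, bool]:
    """Shift of ``cur`` relative to ``prev`` for one 3D frame pair."""
    flat_prev = prev.max() == prev.min()
    flat_cur = cur.max() == cur.min()
    if flat_prev or flat_cur:
        return np.zeros(3), 0.0, True
    mip_prev = prev.max(axis=0)
    mip_cur = cur.max(axis=0)
    # phase_cross_correlation returns the shift to apply to cur to match prev,
    # i.e. -(displacement of cur); negate to report the displacement itself.
    shift_yx, error, _ = phase_cross_correlation(
        mip_prev, mip_cur, upsample_factor=upsample, normalization=None
    )
    prof_prev = prev.sum(axis=(1, 2))
    prof_cur = cur.sum(axis=(1, 2))
    if np.ptp(prof_prev) == 0 or np.ptp(prof_cur) == 0:
        shift_z = np.zeros(1)
    else:
        shift_z, _, _ = phase_cross_correlation(
            prof_prev, prof_cur, upsample_factor=upsample, normalization=None
        )
    score = float(max(0.0, 1.0 - error))
    return -np.array([shift_z[0], shift_yx[0], shift_yx[1]]), score, False


def estimate_shifts(
    series: np.ndarray, reference: int = 0, upsample: int = 10
) -> ShiftSeries:
    """Estimate per-frame translational drift of a (T, Z, Y, X) series.

    Consecutive-frame shifts are accumulated to the reference frame.
    Empty or constant frames contribute zero pairwise shift and are
    flagged low-confidence.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be (T, Z, Y, X)")
    n = series.shape[0]
    if n < 2:
        raise ValueError("need at least two frames")
    if not (0 <= reference < n):
        raise ValueError("reference frame out of range")

    pair = np.zeros((n, 3))
    scores = np.ones(n)
    flags = np.zeros(n, dtype=bool)
    for t in range(1, n):
        pair[t], scores[t], flags[t] = _pairwise_shift(
            series[t - 1], series[t], upsample
        )
    cumulative = np.cumsum(pair, axis=0)
    cumulative -= cumulative[reference]
    return ShiftSeries(
        shifts=cumulative, reference=reference, scores=scores, low_confidence=flags
    )


def apply_shifts(
    series: np.ndarray, shifts: ShiftSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the estimated drift frame by frame.

    Integer shifts are applied by exact translation; fractional ones by
    linear interpolation.  Voxels translated in from outside the volume
    are zero-filled and marked invalid in the returned mask.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be (T, Z, Y, X)")
    if len(shifts) != series.shape[0]:
        raise ValueError("shift series length does not match frame count")
    out = np.empty_like(series)
    valid = np.empty(series.shape, dtype=bool)
    for t in range(series.shape[0]):
        s = -shifts.shifts[t]
        if np.allclose(s, np.round(s)):
            si = np.round(s).astype(int)
            out[t] = _translate_int(series[t], si)
            valid[t] = _translate_int(np.ones(series.shape[1:]), si) > 0
        else:
            out[t] = ndimage.shift(series[t], s, order=1, mode="constant", cval=0.0)
            valid[t] = (
                ndimage.shift(
                    np.ones(series.shape[1:]), s, order=1, mode="constant", cval=0.0
                )
                > 0.999
            )
    return out, valid


def _translate_int(vol: np.ndarray, shift: np.ndarray) -> np.ndarray:
    out = np.zeros_like(vol)
    src = [slice(None)] * vol.ndim
    dst = [slice(None)] * vol.ndim
    for ax, s in enumerate(shift):
        size = vol.shape[ax]
        if abs(s) >= size:
            return out
        if s >= 0:
            dst[ax] = slice(s, size)
            src[ax] = slice(0, size - s)
        else:
            dst[ax] = slice(0, size + s)
            src[ax] = slice(-s, size)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def detrend_tracks(
    track: CentrioleTrack, center_frames: np.ndarray, center_xy: np.ndarray
) -> tuple[CentrioleTrack, np.ndarray]:
    """Express a track relative to the per-frame cell centre.

    x and y are re-expressed as differences from the centre; z is kept in
    registered stack coordinates (the cell centre is a 2D apical-surface
    quantity).  Frames without a centre are dropped; the indices of dropped
    frames are returned alongside the relative track.
    """
    center_frames = np.asarray(center_frames, dtype=int)
    center_xy = np.asarray(center_xy, dtype=float)
    common, ti, ci = np.intersect1d(track.frames, center_frames, return_indices=True)
    if common.size == 0:
        raise ValueError("track and centre series share no frames")
    dropped = np.setdiff1d(track.frames, common)
    xyz = track.xyz[ti].copy()
    xyz[:, :2] -= center_xy[ci]
    rel = CentrioleTrack(
        track_id=track.track_id,
        cell_id=track.cell_id,
        role=track.role,
        frames=common,
        xyz=xyz,
        interpolated=track.interpolated[ti],
        ambiguous=track.ambiguous,
    )
    return rel, dropped
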