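"""Trajectory quantification: centre referencing, distances, speeds, MSD.

All quantities follow the measurement conventions of the live-imaging
analysis: inter-centriole distance is split into the planar (x-y) Euclidean
component and the absolute apical-basal (z) component; migration speed is
the x-y displacement per 10-minute frame of the *centre-relative* position
(i.e. after removing whole-cell drift); mean squared displacement is the
time-averaged estimator and its log-log slope over short lags gives the
anomalous exponent alpha (confined < 1, Brownian ~ 1, directed ~ 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CentrioleTrack
from .spots import CellMaskSeries

__all__ = [
    "CellFrameSeries",
    "DistanceSeries",
    "SpeedSeries",
    "MsdCurve",
    "build_center_series",
    "pair_distances",
    "frame_speeds",
    "msd_curve",
    "radial_series",
    "phase_summary",
]


@dataclass
class CellFrameSeries:
    """Per-frame cell centre with centering mode and polarity axis.

    Before the first frame with a valid reporter mask the mother centriole
    position stands in for the centre (``mc_proxy`` mode); thereafter the
    mask centroid is used.  The polarity axis is a unit 2-vector pointing
    periphery-ward (toward the hair-bundle destination).
    """

    frames: np.ndarray
    center_xy: np.ndarray  # (n, 2) um
    mode: np.ndarray  # per-frame {"mask_centroid", "mc_proxy"}
    apical_radius_um: float
    polarity_axis: np.ndarray  # unit 2-vector
    proxy_switch_frame: int | None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        self.polarity_axis = np.asarray(self.polarity_axis, dtype=float)
        if self.apical_radius_um <= 0:
            raise ValueError("apical radius must be positive")
        norm = np.linalg.norm(self.polarity_axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("polarity axis must be a unit vector")

    def center_at(self, frames: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.frames, frames)
        if np.any(idx >= len(self.frames)) or np.any(self.frames[idx] != frames):
            raise KeyError("requested frames missing from centre series")
        return self.center_xy[idx]


@dataclass
class DistanceSeries:
    """Per-frame planar and axial inter-centriole distances (um)."""

    frames: np.ndarray
    d_xy: np.ndarray
    d_z: np.ndarray


@dataclass
class SpeedSeries:
    """Per-frame x-y migration speed of one centriole (um / frame).

    ``speeds[i]`` is the centre-relative displacement between ``frames[i]``
    and ``frames[i] + 1``; ``valid`` is False where either endpoint was a
    gap-interpolated position (excluded from summary statistics).
    """

    frames: np.ndarray
    speeds: np.ndarray
    valid: np.ndarray
    role: str = "unknown"


@dataclass
class MsdCurve:
    """Time-averaged mean squared displacement and fitted exponent."""

    lag_min: np.ndarray
    msd_um2: np.ndarray
    alpha: float
    fit_lags: tuple[int, int]  # half-open lag-index range used for the fit


def build_center_series(
    masks: CellMaskSeries | None,
    mc_track: CentrioleTrack,
    dc_track: CentrioleTrack | None = None,
    polarity_axis: Sequence[float] | None = None,
    frame_interval: float = 10.0,
    axis_window_hr: float = 3.0,
    apical_radius_um: float | None = None,
) -> CellFrameSeries:
    """Assemble the per-frame cell centre with MC-proxy fallback.

    The centre is the mask centroid wherever a mask exists; for frames
    before the first valid mask the MC position is the proxy.  The polarity
    axis defaults to the unit vector from the mean centre to the DC's mean
    position over the final ``axis_window_hr`` hours; pass
    ``polarity_axis`` to override from tissue anatomy or ground truth.
    """
    all_frames = np.asarray(mc_track.frames, dtype=int)
    mask_frames = masks.frames if masks is not None and len(masks.frames) else np.array([], int)
    switch = int(mask_frames[0]) if mask_frames.size else None

    frames, centers, modes = [], [], []
    for i, f in enumerate(all_frames):
        in_mask = mask_frames.size and f in mask_frames
        if in_mask:
            j = int(np.flatnonzero(mask_frames == f)[0])
            frames.append(f)
            centers.append(masks.centroids_um[j])
            modes.append("mask_centroid")
        elif switch is None or f < switch:
            frames.append(f)
            centers.append(mc_track.xyz[i, :2])
            modes.append("mc_proxy")
        elif masks is not None:
            # after the first mask frame, fill gaps with the nearest mask
            # centroid rather than reverting to the proxy
            j = int(np.argmin(np.abs(mask_frames - f)))
            frames.append(f)
            centers.append(masks.centroids_um[j])
            modes.append("mask_centroid")
    if not frames:
        raise ValueError("no frame has either a mask or an MC position")

    frames = np.array(frames, dtype=int)
    centers = np.array(centers, dtype=float)

    if apical_radius_um is None:
        apical_radius_um = (
            float(np.mean(masks.radii_um)) if masks is not None and len(masks.frames) else 4.0
        )

    if polarity_axis is not None:
        axis = np.asarray(polarity_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        if dc_track is None:
            raise ValueError("need a DC track (or explicit axis) to orient the cell")
        window = max(int(round(axis_window_hr * 60.0 / frame_interval)), 1)
        late = dc_track.frames >= (dc_track.frames.max() - window + 1)
        dc_late = dc_track.xyz[late, :2].mean(axis=0)
        v = dc_late - centers.mean(axis=0)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate polarity axis (DC at the mean centre)")
        axis = v / n

    return CellFrameSeries(
        frames=frames,
        center_xy=centers,
        mode=np.array(modes),
        apical_radius_um=float(apical_radius_um),
        polarity_axis=axis,
        proxy_switch_frame=switch,
    )


def pair_distances(mc: CentrioleTrack, dc: CentrioleTrack) -> DistanceSeries:
    """Planar and axial distances between the two centrioles per frame."""
    common = mc.common_frames(dc)
    if common.size == 0:
        raise ValueError("tracks share no frames")
    a = mc.at_frames(common)
    b = dc.at_frames(common)
    d_xy = np.linalg.norm(a[:, :2] - b[:, :2], axis=1)
    d_z = np.abs(a[:, 2] - b[:, 2])
    return DistanceSeries(frames=common, d_xy=d_xy, d_z=d_z)


def frame_speeds(track: CentrioleTrack, centers: CellFrameSeries) -> SpeedSeries:
    """x-y migration speed per frame on centre-relative coordinates."""
    common = np.intersect1d(track.frames, centers.frames)
    if common.size < 2:
        raise ValueError("need at least two frames with a defined centre")
    pos = track.at_frames(common)[:, :2] - centers.center_at(common)
    idx = np.searchsorted(track.frames, common)
    interp = track.interpolated[idx]
    consecutive = np.diff(common) == 1
    speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    valid = consecutive & ~interp[:-1] & ~interp[1:]
    return SpeedSeries(
        frames=common[:-1][consecutive],
        speeds=speeds[consecutive],
        valid=valid[consecutive],
        role=track.role,
    )


def msd_curve(
    rel_xy: np.ndarray,
    max_lag: int = 50,
    frame_interval: float = 10.0,
    fit_max_lag: int = 10,
) -> MsdCurve:
    """Time-averaged MSD of a centre-relative x-y trajectory.

    ``MSD(tau) = mean_t |r(t + tau) - r(t)|^2`` over all start frames; the
    exponent alpha is the log-log least-squares slope over lags
    ``1..min(fit_max_lag, max_lag)``.
    """
    rel_xy = np.asarray(rel_xy, dtype=float)
    n = len(rel_xy)
    if n < 10:
        raise ValueError("need at least 10 frames for an MSD curve")
    max_lag = min(max_lag, n - 1)
    lags = np.arange(0, max_lag + 1)
    msd = np.zeros(len(lags))
    for i, tau in enumerate(lags[1:], start=1):
        disp = rel_xy[tau:] - rel_xy[:-tau]
        msd[i] = np.mean(np.sum(disp**2, axis=1))
    fit_hi = min(fit_max_lag, max_lag) + 1
    fit_lags = lags[1:fit_hi]
    with np.errstate(divide="ignore"):
        slope, _ = np.polyfit(np.log(fit_lags), np.log(msd[1:fit_hi]), 1)
    return MsdCurve(
        lag_min=lags * frame_interval,
        msd_um2=msd,
        alpha=float(slope),
        fit_lags=(1, fit_hi),
    )


def radial_series(
    track: CentrioleTrack, centers: CellFrameSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial and signed-axis coordinates of a track.

    Returns ``(frames, r, s)`` where ``r`` is the x-y distance from the
    cell centre and ``s`` the projection of the centre-relative position
    onto the polarity axis (positive = periphery-ward / lateral).
    """
    common = np.intersect1d(track.frames, centers.frames)
    if common.size == 0:
        raise ValueError("track and centre series share no frames")
    rel = track.at_frames(common)[:, :2] - centers.center_at(common)
    r = np.linalg.norm(rel, axis=1)
    s = rel @ centers.polarity_axis
    return common, r, s


def phase_summary(
    distances: DistanceSeries,
    speeds: dict[str, SpeedSeries],
    phase2_entry_frame: int | None,
    lat_rule: bool = False,
    last_n_phase1: int = 30,
) -> pd.DataFrame:
    """Per-phase summary of distances and speeds.

    One row per phase with mean d_xy, mean d_z and per-centriole mean/max
    speed.  With ``lat_rule`` (the lateral-hair-cell convention) Phase-I
    averages use only the last ``last_n_phase1`` frames before Phase-II
    entry, dropping earlier frames that may predate hair-cell identity.
    Phases without frames yield NaN rows.
    """
    entry = phase2_entry_frame
    rows = []
    for phase in ("I", "II"):
        if entry is None:
            sel_d = distances.frames >= 0 if phase == "I" else np.zeros_like(
                distances.frames, dtype=bool
            )
        elif phase == "I":
            sel_d = distances.frames < entry
            if lat_rule:
                sel_d &= distances.frames >= entry - last_n_phase1
        else:
            sel_d = distances.frames >= entry
        row = {
            "phase": phase,
            "n_frames": int(sel_d.sum()),
            "mean_d_xy": float(distances.d_xy[sel_d].mean()) if sel_d.any() else np.nan,
            "mean_d_z": float(distances.d_z[sel_d].mean()) if sel_d.any() else np.nan,
        }
        for role, sp in speeds.items():
            if entry is None:
                sel_s = (
                    np.ones_like(sp.frames, dtype=bool)
                    if phase == "I"
                    else np.zeros_like(sp.frames, dtype=bool)
                )
            elif phase == "I":
                sel_s = sp.frames < entry
                if lat_rule:
                    sel_s &= sp.frames >= entry - last_n_phase1
            else:
                sel_s = sp.frames >= entry
            sel_s = sel_s & sp.valid
            row[f"mean_speed_{role.lower()}"] = (
                float(sp.speeds[sel_s].mean()) if sel_s.any() else np.nan
            )
            row[f"max_speed_{role.lower()}"] = (
                float(sp.speeds[sel_s].max()) if sel_s.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
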