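"""Synthetic two-centriole dynamics and rendering to calibrated image series.

The generator emulates the stereotyped behaviour of the mother (MC) and
daughter (DC) centrioles in nascent vestibular hair cells as seen in 3D
time-lapse recordings:

* **Phase I** — the MC sits near the apical cell centre while the DC moves
  rapidly and sporadically around it.  Both are modelled as tightly
  tethered (mean-reverting) random walks updated at the 10-minute frame
  resolution; per-frame x-y displacements are truncated at the observed
  bounds (DC <= ~1.2 um/frame, MC <= ~0.5 um/frame).
* **Phase II** — from a scheduled entry frame the DC migrates at a capped
  speed toward a peripheral anchor at radius ``rho * R`` along the cell's
  polarity axis; the MC follows the DC's bearing after a configurable lag
  and anchors slightly more centrally.  The apical-basal (z) gap between
  the centrioles shrinks from Phase I to Phase II.
* **Perturbations** — an ``emx2_switch`` flips the polarity axis at its
  start frame (trajectory reversal); ``nocodazole`` replaces directed
  migration by a recall toward the cell centre for the duration of its
  window, with amplified DC wander, and restores the prior regime after
  washout.
* A cytoplasmic reporter (tdTomato-like) turns on at a configurable frame
  and ramps linearly; whole-cell drift can be added to both the truth and
  the rendered images.

Rendered image series are two channels: channel 0 holds isotropic 3D
Gaussian spots at the centriole positions, channel 1 a filled disk of the
apical radius scaled by the reporter curve, both corrupted by Poisson
photon noise plus Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import AcquisitionGeometry, CentrioleTrack, write_tracks_csv

__all__ = [
    "SimulationParams",
    "Perturbation",
    "NoiseModel",
    "CellGroundTruth",
    "simulate_cell",
    "simulate_cohort",
    "render_image_series",
    "render_frame",
    "inject_drift",
    "inject_track_drift",
    "export_ground_truth",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-centriole dynamics model.

    Rates are per 10-minute frame unless noted.  Defaults are calibrated so
    that per-frame x-y steps stay within the observed bounds (DC up to
    ~1.2 um, MC not exceeding 0.5 um per frame) while the DC's step
    distribution clearly dominates the MC's.
    """

    apical_radius_R: float = 4.0  # um
    n_frames: int = 250
    frame_interval: float = 10.0  # min

    # Phase-I tethered wander (per-axis Gaussian step scale, um/frame)
    sigma_mc: float = 0.08
    sigma_dc: float = 0.22
    # hard per-frame x-y step caps, um (observed bounds)
    max_step_mc: float = 0.5
    max_step_dc: float = 1.2

    # Phase-II directed migration
    phase2_entry_frame: int = 100
    drift_speed_phase2: float = 0.4  # DC directed speed, um/frame
    mc_follow_speed: float = 0.25  # MC directed speed, um/frame
    mc_follow_lag: int = 6  # frames after entry before the MC follows
    peripheral_fraction: float = 0.85  # DC anchor radius as fraction of R
    mc_peripheral_inset: float = 0.7  # MC anchors this much inside the DC, um
    sigma_phase2: float = 0.15  # wander around the peripheral anchor, um/frame

    # apical-basal geometry (z)
    z_center: float = 3.0  # um, apical-surface plane of the cell
    z_gap_phase1: float = 1.0  # MC above DC, um
    z_gap_phase2: float = 0.3  # um
    sigma_z: float = 0.12  # z jitter per centriole, um/frame

    # polarity axis: unit 2-vector pointing periphery-ward (lateral)
    polarity_axis: tuple[float, float] = (1.0, 0.0)

    # optional late paired recentering (bare-zone stage)
    recenter_pair: bool = False
    recenter_start_frame: int | None = None
    recenter_fraction: float = 0.3  # target radius fraction of R

    # reporter kinetics (arbitrary units)
    reporter_onset_frame: int = 0
    reporter_ramp_rate: float = 2.0  # AU / frame after onset
    reporter_background: float = 20.0  # AU
    reporter_noise_sd: float = 4.0  # AU, measurement noise

    # whole-cell drift, um / frame (x, y)
    cell_drift_velocity: tuple[float, float] = (0.0, 0.0)

    # disable Phase-I tethering (pure diffusion; for calibration checks)
    untethered: bool = False

    def __post_init__(self) -> None:
        arr = np.array(
            [
                self.apical_radius_R,
                self.sigma_mc,
                self.sigma_dc,
                self.drift_speed_phase2,
                self.mc_follow_speed,
                self.sigma_phase2,
                self.z_gap_phase1,
                self.z_gap_phase2,
                self.sigma_z,
                *self.polarity_axis,
                *self.cell_drift_velocity,
            ],
            dtype=float,
        )
        if not np.all(np.isfinite(arr)):
            raise ValueError("simulation parameters must be finite")
        if self.apical_radius_R <= 0:
            raise ValueError("apical_radius_R must be positive")
        if min(self.sigma_mc, self.sigma_dc, self.sigma_phase2, self.sigma_z) < 0:
            raise ValueError("noise scales must be non-negative")
        if not (0.0 < self.peripheral_fraction <= 1.0):
            raise ValueError("peripheral_fraction must be in (0, 1]")
        if np.hypot(*self.polarity_axis) == 0:
            raise ValueError("polarity_axis must be non-zero")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    @property
    def axis_unit(self) -> np.ndarray:
        a = np.asarray(self.polarity_axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass(frozen=True)
class Perturbation:
    """A timed experimental perturbation.

    ``emx2_switch`` flips the polarity axis sign at ``start``; ``end`` is
    ignored.  ``nocodazole`` recalls both centrioles to the cell centre at
    ``recall_speed`` during ``[start, end)`` and amplifies DC wander by
    ``wander_factor``; prior dynamics resume at ``end`` (washout).
    """

    kind: str  # {"emx2_switch", "nocodazole"}
    start: int
    end: int | None = None
    recall_speed: float = 0.5  # um/frame toward centre (nocodazole)
    wander_factor: float = 1.5  # DC sigma multiplier during the window

    def __post_init__(self) -> None:
        if self.kind not in ("emx2_switch", "nocodazole"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "nocodazole" and self.end is None:
            raise ValueError("nocodazole perturbation requires an end frame")
        if self.end is not None and self.end <= self.start:
            raise ValueError("perturbation window must be non-empty")

    def validate_window(self, n_frames: int) -> None:
        end = self.start + 1 if self.end is None else self.end
        if self.start < 0 or end > n_frames:
            raise ValueError(
                f"perturbation window [{self.start}, {end}) outside recording "
                f"of {n_frames} frames"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian camera noise for rendering.

    ``spot_peak_photons`` sets the photon count at a spot peak; with
    Gaussian read noise ``read_sigma`` the default peak SNR is ~10.
    """

    spot_peak_photons: float = 120.0
    reporter_peak_photons: float = 60.0
    background_photons: float = 1.0
    read_sigma: float = 1.0
    enabled: bool = True


@dataclass
class CellGroundTruth:
    """Ground truth for one simulated hair cell."""

    cell_id: int
    params: SimulationParams
    mc: np.ndarray  # (n, 3) x, y, z um
    dc: np.ndarray  # (n, 3)
    cell_center: np.ndarray  # (n, 2) x, y um
    polarity_axis: np.ndarray  # unit 2-vector, original periphery-ward bearing
    phase2_entry_frame: int
    late_phase2_frame: int | None
    mode_label: str  # {"direct", "reversal", "none"}
    axis_flip_frame: int | None
    reversal_arrival_frame: int | None  # first frame signed DC coord <= -1 um
    reporter_detectable_frame: int | None  # analytic 3-sigma ramp crossing
    reporter_intensity: np.ndarray  # (n,) noise-free AU incl. background
    drift: np.ndarray  # (n, 2) cumulative whole-cell drift, um
    peripheral_loss_frame: int | None = None  # nocodazole: DC r < 0.6 R
    perturbations: tuple[Perturbation, ...] = ()
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.mc)

    def mc_track(self) -> CentrioleTrack:
        return CentrioleTrack(
            track_id=2 * self.cell_id,
            cell_id=self.cell_id,
            role="MC",
            frames=np.arange(self.n_frames),
            xyz=self.mc.copy(),
        )

    def dc_track(self) -> CentrioleTrack:
        return CentrioleTrack(
            track_id=2 * self.cell_id + 1,
            cell_id=self.cell_id,
            role="DC",
            frames=np.arange(self.n_frames),
            xyz=self.dc.copy(),
        )

    def signed_dc(self) -> np.ndarray:
        """Signed coordinate of the DC along the original polarity axis."""
        rel = self.dc[:, :2] - self.cell_center
        return rel @ self.polarity_axis


def _clip_step(step: np.ndarray, cap: float) -> np.ndarray:
    n = np.linalg.norm(step)
    if n > cap:
        step = step * (cap / n)
    return step


def _toward(pos: np.ndarray, target: np.ndarray, speed: float) -> np.ndarray:
    """Displacement toward ``target`` capped at ``speed`` (reaches exactly)."""
    d = target - pos
    n = np.linalg.norm(d)
    if n <= speed:
        return d
    return d * (speed / n)


def simulate_cell(
    params: SimulationParams,
    perturbations: Sequence[Perturbation] = (),
    seed: int = 0,
    cell_id: int = 0,
) -> CellGroundTruth:
    """Simulate one cell's MC/DC trajectories with ground-truth events.

    The dynamics are a discrete-time tethered random walk: each frame the
    centriole takes a deterministic step toward its current regime target
    (cell centre, the MC, or a peripheral anchor) capped at the regime
    speed, plus isotropic Gaussian wander; the total x-y step is truncated
    at the per-centriole observed bound.
    """
    p = params
    for pert in perturbations:
        pert.validate_window(p.n_frames)
    rng = np.random.default_rng(seed)
    n = p.n_frames
    entry = int(p.phase2_entry_frame)

    axis0 = p.axis_unit
    flips = sorted(q.start for q in perturbations if q.kind == "emx2_switch")
    noc = [q for q in perturbations if q.kind == "nocodazole"]

    # whole-cell drift (cumulative)
    drift = np.outer(np.arange(n), np.asarray(p.cell_drift_velocity, dtype=float))
    center0 = np.zeros(2)

    mc = np.empty((n, 3))
    dc = np.empty((n, 3))
    mc_xy = center0.copy()
    dc_xy = center0 + rng.normal(0, p.sigma_dc, 2)

    rho_r = p.peripheral_fraction * p.apical_radius_R
    mc_r = max(rho_r - p.mc_peripheral_inset, 0.0)

    for t in range(n):
        axis = axis0 * (-1.0 if any(f <= t for f in flips) else 1.0)
        in_drug = any(q.start <= t < q.end for q in noc)
        phase2 = t >= entry
        recenter = (
            p.recenter_pair
            and p.recenter_start_frame is not None
            and t >= p.recenter_start_frame
        )

        if t > 0:
            if in_drug:
                q = next(q for q in noc if q.start <= t < q.end)
                step_mc = _toward(mc_xy, center0, q.recall_speed) + rng.normal(
                    0, p.sigma_mc, 2
                )
                step_dc = _toward(dc_xy, center0, q.recall_speed) + rng.normal(
                    0, p.sigma_dc * q.wander_factor, 2
                )
            elif recenter:
                tgt = center0 + p.recenter_fraction * p.apical_radius_R * axis
                step_dc = _toward(dc_xy, tgt, p.drift_speed_phase2) + rng.normal(
                    0, p.sigma_phase2, 2
                )
                step_mc = _toward(
                    mc_xy, tgt - p.mc_peripheral_inset * axis, p.mc_follow_speed
                ) + rng.normal(0, p.sigma_mc, 2)
            elif not phase2:
                if p.untethered:
                    step_mc = rng.normal(0, p.sigma_mc, 2)
                    step_dc = rng.normal(0, p.sigma_dc, 2)
                else:
                    step_mc = _toward(mc_xy, center0, p.max_step_mc) + rng.normal(
                        0, p.sigma_mc, 2
                    )
                    step_dc = _toward(dc_xy, mc_xy, p.max_step_dc) + rng.normal(
                        0, p.sigma_dc, 2
                    )
            else:
                dc_anchor = center0 + rho_r * axis
                step_dc = _toward(dc_xy, dc_anchor, p.drift_speed_phase2) + rng.normal(
                    0, p.sigma_phase2, 2
                )
                if t >= entry + p.mc_follow_lag:
                    mc_anchor = center0 + mc_r * axis
                    step_mc = _toward(mc_xy, mc_anchor, p.mc_follow_speed) + rng.normal(
                        0, p.sigma_mc, 2
                    )
                else:
                    step_mc = _toward(mc_xy, center0, p.max_step_mc) + rng.normal(
                        0, p.sigma_mc, 2
                    )
            mc_xy = mc_xy + _clip_step(step_mc, p.max_step_mc)
            dc_xy = dc_xy + _clip_step(step_dc, p.max_step_dc)

        gap = p.z_gap_phase1 if (t < entry or in_drug) else p.z_gap_phase2
        z_mc = p.z_center + rng.normal(0, p.sigma_z)
        z_dc = z_mc - gap + rng.normal(0, p.sigma_z)
        mc[t] = (*(mc_xy + drift[t]), z_mc)
        dc[t] = (*(dc_xy + drift[t]), z_dc)

    center = center0[None, :] + drift

    # reporter: background plus linear ramp after onset (noise-free truth)
    frames = np.arange(n)
    ramp = np.clip(frames - p.reporter_onset_frame, 0, None) * p.reporter_ramp_rate
    reporter = p.reporter_background + np.where(
        frames >= p.reporter_onset_frame, ramp, 0.0
    )
    if p.reporter_noise_sd > 0 and p.reporter_ramp_rate > 0:
        crossing = p.reporter_onset_frame + int(
            np.ceil(3.0 * p.reporter_noise_sd / p.reporter_ramp_rate)
        )
        detectable = crossing if crossing < n else None
    else:
        detectable = p.reporter_onset_frame

    # realized event frames (from the emitted trajectories)
    r_mc = np.linalg.norm(mc[:, :2] - center, axis=1)
    r_dc = np.linalg.norm(dc[:, :2] - center, axis=1)
    thr = 0.6 * p.apical_radius_R
    both = (r_mc >= thr) & (r_dc >= thr)
    late_idx = np.flatnonzero(both)
    late_phase2 = int(late_idx[0]) if late_idx.size else None

    s_dc = (dc[:, :2] - center) @ axis0
    if flips:
        arr_idx = np.flatnonzero((frames >= flips[0]) & (s_dc <= -1.0))
        reversal_arrival = int(arr_idx[0]) if arr_idx.size else None
        mode = "direct" if flips[0] <= entry else "reversal"
    else:
        reversal_arrival = None
        mode = "none"

    loss_frame = None
    if noc:
        w = noc[0]
        loss = np.flatnonzero((frames >= w.start) & (r_dc < thr))
        loss_frame = int(loss[0]) if loss.size else None

    return CellGroundTruth(
        cell_id=cell_id,
        params=p,
        mc=mc,
        dc=dc,
        cell_center=center,
        polarity_axis=axis0,
        phase2_entry_frame=entry,
        late_phase2_frame=late_phase2,
        mode_label=mode,
        axis_flip_frame=flips[0] if flips else None,
        reversal_arrival_frame=reversal_arrival,
        reporter_detectable_frame=detectable,
        reporter_intensity=reporter,
        drift=drift,
        peripheral_loss_frame=loss_frame,
        perturbations=tuple(perturbations),
        seed=seed,
    )


def simulate_cohort(
    params: SimulationParams,
    n: int,
    mode_fractions: dict[str, float] | None = None,
    seed: int = 0,
    exact_assignment: bool = True,
    reversal_delay_frames: int = 40,
    entry_jitter: int = 10,
) -> list[CellGroundTruth]:
    """Simulate ``n`` cells with deterministic per-cell seeds.

    ``mode_fractions`` assigns trajectory modes for ectopic-Emx2 cohorts:
    ``direct`` cells have the axis flipped from frame 0 (the reversed
    target is adopted before any peripheral excursion), ``reversal`` cells
    flip ``reversal_delay_frames`` after Phase-II entry, once the DC is
    already peripheral.  With ``exact_assignment`` the mode counts are
    ``round(n * fraction)``; otherwise modes are drawn per cell.
    Phase-II entry frames are jittered uniformly by ``+-entry_jitter``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    fractions = mode_fractions or {}
    total = sum(fractions.values())
    if fractions and abs(total - 1.0) > 1e-9:
        raise ValueError("mode fractions must sum to 1")

    master = np.random.SeedSequence(seed)
    cell_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n)]
    assign_rng = np.random.default_rng(cell_seeds[0] ^ 0x5EED)

    modes: list[str]
    if not fractions:
        modes = ["none"] * n
    elif exact_assignment:
        names = sorted(fractions)
        counts = {m: int(round(n * fractions[m])) for m in names}
        # fix rounding so counts sum to n (largest fraction absorbs the rest)
        diff = n - sum(counts.values())
        counts[max(names, key=lambda m: fractions[m])] += diff
        modes = [m for m in names for _ in range(counts[m])]
    else:
        names = sorted(fractions)
        probs = [fractions[m] for m in names]
        modes = [names[i] for i in assign_rng.choice(len(names), size=n, p=probs)]

    cohort = []
    for i in range(n):
        rng_i = np.random.default_rng(cell_seeds[i])
        jitter = int(rng_i.integers(-entry_jitter, entry_jitter + 1)) if entry_jitter else 0
        p_i = params.replace(phase2_entry_frame=params.phase2_entry_frame + jitter)
        perts: list[Perturbation] = []
        if modes[i] == "direct":
            perts.append(Perturbation("emx2_switch", start=0))
        elif modes[i] == "reversal":
            flip = p_i.phase2_entry_frame + reversal_delay_frames
            flip = min(flip, p_i.n_frames - 1)
            perts.append(Perturbation("emx2_switch", start=flip))
        cohort.append(
            simulate_cell(p_i, perts, seed=cell_seeds[i], cell_id=i)
        )
    return cohort


def _um_to_voxel(xyz: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """(x, y, z) um -> (z, y, x) voxel index coordinates."""
    x, y, z = xyz
    return np.array(
        [z / geometry.z_step, y / geometry.pixel_size_xy, x / geometry.pixel_size_xy]
    )


def render_frame(
    spots_um: Sequence[np.ndarray],
    geometry: AcquisitionGeometry,
    sigma_xy_px: float = 1.5,
    sigma_z_planes: float = 1.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Render isotropic 3D Gaussian spots into a single noiseless volume."""
    nz, ny, nx = geometry.stack_shape
    vol = np.zeros((nz, ny, nx), dtype=float)
    for xyz in spots_um:
        czyx = _um_to_voxel(np.asarray(xyz, dtype=float), geometry)
        if np.any(czyx < -0.5) or np.any(czyx > np.array([nz, ny, nx]) - 0.5):
            raise ValueError(f"spot at {xyz} outside the rendered volume")
        half = np.array(
            [int(np.ceil(4 * sigma_z_planes)), int(np.ceil(4 * sigma_xy_px)),
             int(np.ceil(4 * sigma_xy_px))]
        )
        lo = np.maximum(np.floor(czyx - half).astype(int), 0)
        hi = np.minimum(np.ceil(czyx + half).astype(int) + 1, [nz, ny, nx])
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        g = np.exp(
            -(
                (zz - czyx[0]) ** 2 / (2 * sigma_z_planes**2)
                + (yy - czyx[1]) ** 2 / (2 * sigma_xy_px**2)
                + (xx - czyx[2]) ** 2 / (2 * sigma_xy_px**2)
            )
        )
        vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * g
    return vol


def render_image_series(
    truth: CellGroundTruth,
    geometry: AcquisitionGeometry | None = None,
    noise: NoiseModel | None = None,
    center_offset_um: tuple[float, float] | None = None,
    sigma_xy_px: float = 1.5,
    sigma_z_planes: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a ground truth to a two-channel (T, C, Z, Y, X) series.

    The simulated cell (centred at its own origin) is placed at the stack
    centre unless ``center_offset_um`` overrides the placement.  Returns
    the voxel series (float photons) and a calibration metadata dict.
    """
    geometry = geometry or AcquisitionGeometry(n_frames=truth.n_frames)
    noise = noise or NoiseModel()
    nz, ny, nx = geometry.stack_shape
    if center_offset_um is None:
        center_offset_um = (
            nx * geometry.pixel_size_xy / 2.0,
            ny * geometry.pixel_size_xy / 2.0,
        )
    off = np.array([*center_offset_um, 0.0])
    rng = np.random.default_rng(seed)

    n = truth.n_frames
    series = np.zeros((n, 2, nz, ny, nx), dtype=float)
    reporter = truth.reporter_intensity
    rep_scale = reporter - truth.params.reporter_background
    rep_max = rep_scale.max() if rep_scale.max() > 0 else 1.0

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for t in range(n):
        spots = [truth.mc[t] + off, truth.dc[t] + off]
        series[t, 0] = render_frame(
            spots, geometry, sigma_xy_px, sigma_z_planes, noise.spot_peak_photons
        )
        # channel 1: filled apical disk, intensity follows the reporter ramp
        level = rep_scale[t] / rep_max * noise.reporter_peak_photons
        if level > 0:
            c_um = truth.cell_center[t] + off[:2]
            cx = c_um[0] / geometry.pixel_size_xy
            cy = c_um[1] / geometry.pixel_size_xy
            rad = truth.params.apical_radius_R / geometry.pixel_size_xy
            disk = ((xx - cx) ** 2 + (yy - cy) ** 2) <= rad**2
            zc = int(round(truth.params.z_center / geometry.z_step))
            for dz in (-1, 0, 1):
                zi = zc + dz
                if 0 <= zi < nz:
                    series[t, 1, zi][disk] = level
    series += noise.background_photons
    if noise.enabled:
        series = rng.poisson(series).astype(float)
        series += rng.normal(0.0, noise.read_sigma, series.shape)

    metadata = {
        "axes": "TCZYX",
        "pixel_size_xy_um": geometry.pixel_size_xy,
        "z_step_um": geometry.z_step,
        "frame_interval_min": geometry.frame_interval,
        "stack_shape": list(geometry.stack_shape),
        "n_frames": n,
        "center_offset_um": list(center_offset_um),
        "seed": seed,
    }
    return series, metadata


def inject_drift(
    series: np.ndarray, shifts: np.ndarray, subvoxel: bool = False
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Translate each frame of a (T, Z, Y, X) series by per-frame shifts.

    ``shifts`` is (T, 3) in (z, y, x) voxels: the displacement applied to
    frame ``t``'s content.  Integer shifts are applied by exact translation,
    fractional ones by linear interpolation.  Returns the shifted series,
    the true shifts (the recovery oracle) and a flag set when any shift
    pushes more than half the frame out of view.
    """
    from scipy import ndimage

    shifts = np.asarray(shifts, dtype=float)
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    if shifts.shape != (series.shape[0], 3):
        raise ValueError("shifts must be (n_frames, 3)")
    out = np.empty_like(series, dtype=float)
    clipped = False
    half = np.array(series.shape[1:]) / 2.0
    for t in range(series.shape[0]):
        s = shifts[t]
        if np.any(np.abs(s) > half):
            clipped = True
        if not subvoxel and np.allclose(s, np.round(s)):
            out[t] = _integer_translate(series[t], np.round(s).astype(int))
        else:
            out[t] = ndimage.shift(series[t], s, order=1, mode="constant", cval=0.0)
    return out, shifts.copy(), clipped


def _integer_translate(vol: np.ndarray, shift: np.ndarray) -> np.ndarray:
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


def inject_track_drift(
    truth: CellGroundTruth, drift_xy: np.ndarray
) -> CellGroundTruth:
    """Add a common per-frame x-y drift to both centrioles and the centre."""
    drift_xy = np.asarray(drift_xy, dtype=float)
    if drift_xy.shape != (truth.n_frames, 2):
        raise ValueError("drift must be (n_frames, 2)")
    if not np.all(np.isfinite(drift_xy)):
        raise ValueError("drift must be finite")
    new = dataclasses.replace(
        truth,
        mc=truth.mc + np.c_[drift_xy, np.zeros(len(drift_xy))],
        dc=truth.dc + np.c_[drift_xy, np.zeros(len(drift_xy))],
        cell_center=truth.cell_center + drift_xy,
        drift=truth.drift + drift_xy,
    )
    return new


def export_ground_truth(
    truth_or_cohort: CellGroundTruth | Sequence[CellGroundTruth],
    out_dir: str | Path,
    prefix: str = "ground_truth",
) -> dict[str, Path]:
    """Write tracks CSV plus a params/seed metadata JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = (
        [truth_or_cohort]
        if isinstance(truth_or_cohort, CellGroundTruth)
        else list(truth_or_cohort)
    )
    tracks = []
    meta = []
    for truth in cohort:
        tracks.extend([truth.mc_track(), truth.dc_track()])
        meta.append(
            {
                "cell_id": truth.cell_id,
                "seed": truth.seed,
                "mode_label": truth.mode_label,
                "phase2_entry_frame": truth.phase2_entry_frame,
                "late_phase2_frame": truth.late_phase2_frame,
                "axis_flip_frame": truth.axis_flip_frame,
                "reversal_arrival_frame": truth.reversal_arrival_frame,
                "reporter_detectable_frame": truth.reporter_detectable_frame,
                "peripheral_loss_frame": truth.peripheral_loss_frame,
                "polarity_axis": truth.polarity_axis.tolist(),
                "params": dataclasses.asdict(truth.params),
            }
        )
    csv_path = out_dir / f"{prefix}_tracks.csv"
    write_tracks_csv(tracks, csv_path, cohort[0].params.frame_interval)
    json_path = out_dir / f"{prefix}_meta.json"
    json_path.write_text(json.dumps(meta, indent=2))
    return {"tracks": csv_path, "metadata": json_path}
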