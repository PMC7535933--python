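"""Cell masking, centriole spot detection, track linking and role assignment.

The reporter channel defines the cell: per-frame 2D maximum projections are
thresholded (Otsu by default), size-filtered, and components are linked
across frames by maximum overlap.  The centriole channel is restricted to
(dilated) cell masks so that spots outside reporter-positive cells are
eliminated, then spots are detected by a Laplacian-of-Gaussian filter with
subvoxel refinement.  Linking assumes at most one MC and one DC per cell
(hair cells are post-mitotic), so frame-to-frame assignment compares both
pairings of at most two spots and keeps the one with minimal summed
displacement under a distance gate.  The mother centriole is the track with
the greater mean apical (z) position over the common frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .core import AcquisitionGeometry, CentrioleTrack

__all__ = [
    "CellMaskSeries",
    "SpotDetection",
    "segment_cells",
    "mask_centriole_channel",
    "detect_spots",
    "link_tracks",
    "assign_mc_dc",
]


@dataclass
class CellMaskSeries:
    """Per-frame 2D binary masks for one tracked cell.

    ``frames`` lists frames with a nonempty mask; ``centroids_um`` are the
    (x, y) mask centroids and ``radii_um`` the equivalent-circle radii.
    """

    cell_id: int
    frames: np.ndarray
    masks: list[np.ndarray]
    centroids_um: np.ndarray  # (n, 2) x, y
    radii_um: np.ndarray

    @property
    def first_frame(self) -> int | None:
        return int(self.frames[0]) if len(self.frames) else None

    def mask_at(self, frame: int) -> np.ndarray | None:
        idx = np.flatnonzero(self.frames == frame)
        return self.masks[int(idx[0])] if idx.size else None


@dataclass
class SpotDetection:
    """One subvoxel spot detection in a single 3D frame."""

    frame: int
    x_um: float
    y_um: float
    z_um: float
    intensity: float
    quality: float
    cell_id: int | None = None
    merged: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um])


def segment_cells(
    reporter: np.ndarray,
    geometry: AcquisitionGeometry,
    threshold: str | float = "otsu",
    min_area_um2: float = 5.0,
    noise_k: float = 5.0,
) -> list[CellMaskSeries]:
    """Segment reporter-positive cells in a (T, Z, Y, X) channel.

    Frames whose projection lacks real signal (all background, pre-onset)
    yield no mask, so the first nonempty mask frame tracks reporter onset:
    the mean suprathreshold intensity must clear the robust noise band
    ``median + noise_k * 1.4826 * MAD`` of the projection to count as
    signal.  Components are linked across frames by maximum pixel overlap
    (bridging short mask dropouts of up to ``link_memory`` frames).
    """
    reporter = np.asarray(reporter, dtype=float)
    if reporter.ndim != 4:
        raise ValueError("reporter channel must be (T, Z, Y, X)")
    px = geometry.pixel_size_xy
    min_area_px = max(int(round(min_area_um2 / px**2)), 1)

    # per-frame labelled masks
    per_frame: list[np.ndarray] = []
    for t in range(reporter.shape[0]):
        mip = reporter[t].max(axis=0)
        labels = np.zeros(mip.shape, dtype=int)
        if np.ptp(mip) > 0:
            if threshold == "otsu":
                thr = threshold_otsu(mip)
            else:
                thr = float(threshold)
            med = np.median(mip)
            mad = np.median(np.abs(mip - med))
            fg = mip > thr
            if fg.any() and mip[fg].mean() > med + noise_k * 1.4826 * mad:
                labels = label(fg)
                for region in regionprops(labels):
                    if region.area < min_area_px:
                        labels[labels == region.label] = 0
        per_frame.append(labels)

    # overlap-based identity linking; a short mask dropout does not split
    # the cell identity (overlap is taken with the last nonempty frame
    # within ``link_memory`` frames)
    link_memory = 5
    cells: dict[int, dict] = {}
    prev: tuple[int, np.ndarray, dict[int, int]] | None = None
    next_id = 0
    for t, labels in enumerate(per_frame):
        regions = regionprops(labels)
        if not regions:
            continue
        owner: dict[int, int] = {}
        for region in regions:
            mask = labels == region.label
            cell_id = None
            if prev is not None and t - prev[0] <= link_memory:
                overlap = np.bincount(prev[1][mask].ravel())
                overlap[0] = 0
                if overlap.size and overlap.max() > 0:
                    cell_id = prev[2].get(int(np.argmax(overlap)))
            if cell_id is None:
                cell_id = next_id
                next_id += 1
                cells[cell_id] = {"frames": [], "masks": [], "cent": [], "rad": []}
            owner[region.label] = cell_id
            cy, cx = region.centroid
            cells[cell_id]["frames"].append(t)
            cells[cell_id]["masks"].append(mask)
            cells[cell_id]["cent"].append((cx * px, cy * px))
            cells[cell_id]["rad"].append(np.sqrt(region.area / np.pi) * px)
        prev = (t, labels, owner)

    return [
        CellMaskSeries(
            cell_id=cid,
            frames=np.array(d["frames"], dtype=int),
            masks=d["masks"],
            centroids_um=np.array(d["cent"], dtype=float).reshape(-1, 2),
            radii_um=np.array(d["rad"], dtype=float),
        )
        for cid, d in sorted(cells.items())
    ]


def mask_centriole_channel(
    spot_channel: np.ndarray,
    masks: Sequence[CellMaskSeries],
    geometry: AcquisitionGeometry,
    dilation_um: float = 0.5,
) -> np.ndarray:
    """Zero the centriole channel outside (dilated) cell masks.

    Spots without overlapping reporter signal are thereby eliminated from
    downstream detection.  Frames where no cell mask exists are zeroed
    entirely.
    """
    spot_channel = np.asarray(spot_channel, dtype=float)
    if spot_channel.ndim != 4:
        raise ValueError("spot channel must be (T, Z, Y, X)")
    n, nz, ny, nx = spot_channel.shape
    radius_px = max(int(round(dilation_um / geometry.pixel_size_xy)), 0)
    selem = disk(radius_px) if radius_px > 0 else None

    out = np.zeros_like(spot_channel)
    for t in range(n):
        union = np.zeros((ny, nx), dtype=bool)
        for series in masks:
            m = series.mask_at(t)
            if m is not None:
                if m.shape != (ny, nx):
                    raise ValueError("mask shape does not match the spot channel")
                union |= m
        if selem is not None and union.any():
            union = ndimage.binary_dilation(union, structure=selem)
        if union.any():
            out[t] = spot_channel[t] * union[None, :, :]
    return out


def _robust_threshold(response: np.ndarray, volume: np.ndarray, k: float) -> float:
    """Background threshold ``median + k * 1.4826 * MAD`` of the response.

    Statistics are taken over voxels carrying signal (nonzero in the
    volume) so that masked-out regions do not deflate the noise estimate.
    """
    support = volume > 0
    vals = response[support] if support.any() else response.ravel()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    return med + k * 1.4826 * mad


def detect_spots(
    volume: np.ndarray,
    geometry: AcquisitionGeometry,
    frame: int = 0,
    sigma_xy_px: float = 1.5,
    sigma_z_planes: float = 1.0,
    threshold_k: float = 5.0,
    merge_width_factor: float = 1.07,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one 3D volume.

    A scale-matched Laplacian-of-Gaussian response is thresholded at
    ``median + threshold_k * 1.4826 * MAD``; local maxima are refined to
    subvoxel precision by an intensity-weighted centroid over a 3x3 x-y
    neighbourhood and a 3-plane parabolic fit in z.  Detections whose
    intensity-weighted width along the wider principal axis exceeds
    ``merge_width_factor`` times the nominal spot width are flagged as
    possible merges of two unresolved spots (the factor sits between the
    measured single-spot and two-spot width distributions at the default
    rendering scale).
    """
    if sigma_xy_px <= 0 or sigma_z_planes <= 0:
        raise ValueError("spot scales must be positive")
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be a single (Z, Y, X) frame")
    nz, ny, nx = volume.shape

    response = -ndimage.gaussian_laplace(
        volume, sigma=(sigma_z_planes, sigma_xy_px, sigma_xy_px)
    )
    thr = _robust_threshold(response, volume, threshold_k)
    # local maxima over a neighbourhood comparable to the spot footprint
    footprint = np.ones((3, 5, 5), dtype=bool)
    maxima = (response == ndimage.maximum_filter(response, footprint=footprint)) & (
        response > thr
    )
    coords = np.argwhere(maxima)

    detections: list[SpotDetection] = []
    for zc, yc, xc in coords:
        # subvoxel x-y: intensity-weighted centroid of a 3x3 patch on the
        # maximum plane (background-subtracted to first order)
        y0, y1 = max(yc - 1, 0), min(yc + 2, ny)
        x0, x1 = max(xc - 1, 0), min(xc + 2, nx)
        patch = volume[zc, y0:y1, x0:x1]
        w = np.clip(patch - patch.min(), 0, None)
        if w.sum() == 0:
            w = np.ones_like(patch)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        y_sub = float((w * yy).sum() / w.sum())
        x_sub = float((w * xx).sum() / w.sum())
        # subvoxel z: parabola through the 3 axial samples at the peak
        if 0 < zc < nz - 1:
            f_m, f_0, f_p = volume[zc - 1 : zc + 2, yc, xc]
            denom = f_m - 2 * f_0 + f_p
            dz = 0.5 * (f_m - f_p) / denom if denom != 0 else 0.0
            z_sub = zc + float(np.clip(dz, -0.5, 0.5))
        else:
            z_sub = float(zc)

        # merge heuristic: second-moment width over a wider window
        r = int(np.ceil(2 * sigma_xy_px)) + 1
        wy0, wy1 = max(yc - r, 0), min(yc + r + 1, ny)
        wx0, wx1 = max(xc - r, 0), min(xc + r + 1, nx)
        wpatch = np.clip(
            volume[zc, wy0:wy1, wx0:wx1] - np.median(volume[zc]), 0, None
        )
        merged = False
        if wpatch.sum() > 0:
            gy, gx = np.mgrid[wy0:wy1, wx0:wx1]
            my = (wpatch * gy).sum() / wpatch.sum()
            mx = (wpatch * gx).sum() / wpatch.sum()
            vy = (wpatch * (gy - my) ** 2).sum() / wpatch.sum()
            vx = (wpatch * (gx - mx) ** 2).sum() / wpatch.sum()
            merged = bool(np.sqrt(max(vy, vx)) > merge_width_factor * sigma_xy_px)

        detections.append(
            SpotDetection(
                frame=frame,
                x_um=x_sub * geometry.pixel_size_xy,
                y_um=y_sub * geometry.pixel_size_xy,
                z_um=z_sub * geometry.z_step,
                intensity=float(volume[zc, yc, xc]),
                quality=float(response[zc, yc, xc]),
                merged=merged,
            )
        )
    detections.sort(key=lambda d: -d.quality)
    return detections


def link_tracks(
    detections: Sequence[SpotDetection],
    gate_um: float = 2.5,
    max_gap: int = 2,
    cell_id: int = 0,
) -> list[CentrioleTrack]:
    """Link per-frame detections into at most two centriole tracks.

    Frame-to-frame assignment minimises summed x-y displacement subject to
    the ``gate_um`` gate (both pairings of <= 2 spots are compared, which
    is optimal here).  A track missing for up to ``max_gap`` frames is
    reconnected with linearly interpolated, flagged positions.  If more
    than two detections appear in a frame the two of highest quality are
    kept and the frame is flagged ambiguous on the resulting tracks.
    When a single detection serves two nearby tracks (an unresolved,
    merged centriole pair) both tracks adopt it, flagged like an
    interpolated position so that it is excluded from speed statistics.
    """
    if gate_um <= 0:
        raise ValueError("gate must be positive")
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []

    ambiguous_any = False
    tracks: list[dict] = []  # each: frames, xyz, interp, last_frame

    for frame in sorted(by_frame):
        dets = sorted(by_frame[frame], key=lambda d: -d.quality)
        if len(dets) > 2:
            dets = dets[:2]
            ambiguous_any = True
        new_pos = [d.xyz for d in dets]

        active = [tr for tr in tracks if frame - tr["last_frame"] <= max_gap + 1]
        if active:
            last_pos = [tr["xyz"][-1] for tr in active]
            matched = _pairing_cost_gated(last_pos, new_pos, active, frame, gate_um)
            assigned = set()
            # unmatched track near an assigned detection: merged pair —
            # let the track share that detection (flagged)
            shared: dict[int, int] = {}
            for i, tr in enumerate(active):
                if matched[i] >= 0 or not new_pos:
                    continue
                gap = frame - tr["last_frame"]
                dists = [
                    np.linalg.norm(np.asarray(tr["xyz"][-1][:2]) - q[:2])
                    for q in new_pos
                ]
                jn = int(np.argmin(dists))
                if jn in [m for m in matched if m >= 0] and dists[jn] <= gate_um * gap:
                    shared[i] = jn
            for i, tr in enumerate(active):
                j = matched[i]
                is_shared = False
                if j < 0 and i in shared:
                    j, is_shared = shared[i], True
                if j < 0:
                    continue
                assigned.add(j)
                gap = frame - tr["last_frame"] - 1
                if gap > 0:
                    start = np.asarray(tr["xyz"][-1])
                    stop = new_pos[j]
                    for g in range(1, gap + 1):
                        frac = g / (gap + 1)
                        tr["frames"].append(tr["last_frame"] + g)
                        tr["xyz"].append(start + frac * (stop - start))
                        tr["interp"].append(True)
                tr["frames"].append(frame)
                tr["xyz"].append(new_pos[j])
                tr["interp"].append(is_shared)
                tr["last_frame"] = frame
            leftovers = [j for j in range(len(new_pos)) if j not in assigned]
        else:
            leftovers = list(range(len(new_pos)))

        for j in leftovers:
            if len(tracks) < 2:
                tracks.append(
                    {
                        "frames": [frame],
                        "xyz": [new_pos[j]],
                        "interp": [False],
                        "last_frame": frame,
                    }
                )
            else:
                ambiguous_any = True

    out = []
    for k, tr in enumerate(tracks):
        out.append(
            CentrioleTrack(
                track_id=k,
                cell_id=cell_id,
                role="unknown",
                frames=np.array(tr["frames"], dtype=int),
                xyz=np.array(tr["xyz"], dtype=float),
                interpolated=np.array(tr["interp"], dtype=bool),
                ambiguous=ambiguous_any,
            )
        )
    return out


def _pairing_cost_gated(last_pos, new_pos, active, frame, gate_um):
    """Assignment with per-track gates scaled by the gap being closed."""
    from itertools import permutations

    n_tr, n_new = len(last_pos), len(new_pos)
    candidates = list(range(n_new)) + [-1] * n_tr
    best_key, best_perm = None, tuple([-1] * n_tr)
    for perm in set(permutations(candidates, n_tr)):
        used = [j for j in perm if j >= 0]
        if len(used) != len(set(used)):
            continue
        cost, ok = 0.0, True
        for i, j in enumerate(perm):
            if j < 0:
                continue
            gap = frame - active[i]["last_frame"]
            d = np.linalg.norm(np.asarray(last_pos[i][:2]) - np.asarray(new_pos[j][:2]))
            if d > gate_um * gap:
                ok = False
                break
            cost += d
        if ok:
            key = (-len(used), cost)
            if best_key is None or key < best_key:
                best_key, best_perm = key, perm
    return best_perm


def assign_mc_dc(
    track_a: CentrioleTrack,
    track_b: CentrioleTrack,
    min_common_frames: int = 5,
    z_tie_um: float = 0.1,
) -> tuple[CentrioleTrack, CentrioleTrack]:
    """Label a track pair as (MC, DC) by mean apicality.

    The mother centriole is the track with the greater mean z over the
    common frames (z increases apically).  When the mean-z difference is
    below ``z_tie_um`` the track with the lower x-y displacement variance
    is called MC and both tracks are flagged ambiguous.
    """
    common = track_a.common_frames(track_b)
    if common.size < min_common_frames:
        raise ValueError(
            f"need >= {min_common_frames} common frames to assign roles"
        )
    za = track_a.at_frames(common)[:, 2].mean()
    zb = track_b.at_frames(common)[:, 2].mean()
    if abs(za - zb) >= z_tie_um:
        mc, dc = (track_a, track_b) if za > zb else (track_b, track_a)
        ambiguous = False
    else:
        va = np.var(np.diff(track_a.at_frames(common)[:, :2], axis=0))
        vb = np.var(np.diff(track_b.at_frames(common)[:, :2], axis=0))
        mc, dc = (track_a, track_b) if va <= vb else (track_b, track_a)
        ambiguous = True
    mc.role, dc.role = "MC", "DC"
    mc.ambiguous = mc.ambiguous or ambiguous
    dc.ambiguous = dc.ambiguous or ambiguous
    return mc, dc
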