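"""End-to-end per-cell analysis on tracked coordinates.

Glues the trajectory, phase and event layers together: given an MC/DC
track pair (from the tracker or from an imported coordinate table) plus an
optional reporter mask series, produces the per-frame analysis table and
the per-cell event summary used by the cohort report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import phases, traj
from .core import CentrioleTrack
from .spots import CellMaskSeries

__all__ = ["CellAnalysis", "analyze_cell", "centers_from_truth"]


def centers_from_truth(truth) -> traj.CellFrameSeries:
    """Build the per-frame centre series from a simulated ground truth.

    Used when analysing ground-truth tracks directly (no rendered reporter
    channel to segment): centre, apical radius and polarity axis are taken
    from the generator record.
    """
    n = truth.n_frames
    return traj.CellFrameSeries(
        frames=np.arange(n),
        center_xy=truth.cell_center.copy(),
        mode=np.array(["mask_centroid"] * n),
        apical_radius_um=truth.params.apical_radius_R,
        polarity_axis=truth.polarity_axis.copy(),
        proxy_switch_frame=None,
    )


@dataclass
class CellAnalysis:
    """Everything the pipeline derives for one cell."""

    cell_id: int
    centers: traj.CellFrameSeries
    distances: traj.DistanceSeries
    speeds: dict[str, traj.SpeedSeries]
    phase2_entry_frame: int | None
    entry_reason: str | None
    late_phase2_frame: int | None
    mode: str
    events: phases.EventRecord
    per_frame: pd.DataFrame
    summary: pd.DataFrame


def analyze_cell(
    mc: CentrioleTrack,
    dc: CentrioleTrack,
    masks: CellMaskSeries | None = None,
    centers: traj.CellFrameSeries | None = None,
    polarity_axis: Sequence[float] | None = None,
    reporter: np.ndarray | None = None,
    drug_window: tuple[int, int] | None = None,
    frame_interval: float = 10.0,
    apical_radius_um: float | None = None,
    lat_rule: bool = False,
    entry_params: dict | None = None,
    event_params: dict | None = None,
) -> CellAnalysis:
    """Quantify one cell from its MC/DC tracks.

    ``polarity_axis`` may come from tissue anatomy or ground truth; when
    omitted it is estimated from the DC's late-recording position.  An
    explicit ``centers`` series (e.g. from ground truth) bypasses the
    mask/MC-proxy assembly.
    """
    if centers is None:
        centers = traj.build_center_series(
            masks,
            mc,
            dc_track=dc,
            polarity_axis=polarity_axis,
            frame_interval=frame_interval,
            apical_radius_um=apical_radius_um,
        )
    distances = traj.pair_distances(mc, dc)
    speeds = {
        "MC": traj.frame_speeds(mc, centers),
        "DC": traj.frame_speeds(dc, centers),
    }
    f_mc, r_mc, s_mc = traj.radial_series(mc, centers)
    f_dc, r_dc, s_dc = traj.radial_series(dc, centers)

    entry_kw = dict(entry_params or {})
    entry, reason = phases.detect_phase2_entry(
        r_dc, centers.apical_radius_um, **entry_kw
    )
    late = phases.detect_late_phase2(r_mc, r_dc, centers.apical_radius_um)

    ev_kw = dict(event_params or {})
    events = phases.perturbation_events(
        s_dc=s_dc,
        r_dc=r_dc,
        reporter=reporter,
        apical_radius_um=centers.apical_radius_um,
        drug_window=drug_window,
        frame_interval=frame_interval,
        **ev_kw,
    )

    summary = traj.phase_summary(distances, speeds, entry, lat_rule=lat_rule)

    common = np.intersect1d(f_mc, f_dc)
    sel_mc = np.isin(f_mc, common)
    sel_dc = np.isin(f_dc, common)
    d_idx = np.isin(distances.frames, common)
    per_frame = pd.DataFrame(
        {
            "frame": common,
            "t_min": common * frame_interval,
            "phase": np.where(
                (entry is not None) & (common >= (entry if entry is not None else 0)),
                "II",
                "I",
            )
            if entry is not None
            else "I",
            "r_mc": r_mc[sel_mc],
            "r_dc": r_dc[sel_dc],
            "s_mc": s_mc[sel_mc],
            "s_dc": s_dc[sel_dc],
            "d_xy": distances.d_xy[d_idx],
            "d_z": distances.d_z[d_idx],
        }
    )
    per_frame["centering_mode"] = [
        centers.mode[np.flatnonzero(centers.frames == f)[0]] for f in common
    ]

    return CellAnalysis(
        cell_id=mc.cell_id,
        centers=centers,
        distances=distances,
        speeds=speeds,
        phase2_entry_frame=entry,
        entry_reason=reason,
        late_phase2_frame=late,
        mode=events.mode,
        events=events,
        per_frame=per_frame,
        summary=summary,
    )
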