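"""Event detection on quantified trajectories.

Operationalises the retroactive trajectory-stage definitions used when
scoring live recordings:

* **Phase-II entry** — the daughter centriole starts moving consistently
  toward the periphery.  Operationally: the earliest frame ``t*`` whose
  following window of ``W`` frames gains at least ``dr_min`` um of radius
  with at least a fraction ``q`` of positive radial increments, provided
  the radius later reaches ``rho * R``.  A least-squares changepoint
  refinement inside the qualifying window pins the entry to the actual
  kink of the radial curve.
* **Late Phase II** — both centrioles peripheral (radius >= ``rho * R``)
  for ``m`` consecutive frames.
* **Trajectory mode** — ``direct`` (straight to the reversed, medial
  destination) versus ``reversal`` (first a sustained lateral excursion,
  then a sustained medial one), scored on the signed-axis DC coordinate.
* **Reporter onset** — first sustained excursion of the reporter intensity
  above ``background mean + k * background sd``.
* **Perturbation events** — reversal latency relative to reporter onset,
  and loss of the DC's peripheral position after drug addition.

All detectors are deterministic given their inputs and parameters, and all
"first frame where" rules return the earliest index with half-open
sustained windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhaseAnnotation",
    "EventRecord",
    "detect_phase2_entry",
    "detect_late_phase2",
    "classify_mode",
    "detect_reporter_onset",
    "perturbation_events",
    "fraction_within",
]


@dataclass
class PhaseAnnotation:
    """Phase labels and the rule parameters that produced them."""

    phase2_entry_frame: int | None
    late_phase2_frame: int | None
    labels: np.ndarray  # per-frame {"I", "II-early", "II-late"}
    params: dict
    reason: str | None = None  # why entry is None, when it is

    def __post_init__(self) -> None:
        if (
            self.phase2_entry_frame is not None
            and self.late_phase2_frame is not None
            and self.late_phase2_frame < self.phase2_entry_frame
        ):
            raise ValueError("late Phase II cannot precede Phase-II entry")


@dataclass
class EventRecord:
    """Per-cell event summary for perturbation experiments."""

    reporter_onset_frame: int | None = None
    reversal_frame: int | None = None
    latency_hr: float | None = None
    drug_window: tuple[int, int] | None = None
    peripheral_loss_frame: int | None = None
    loss_delay_min: float | None = None
    mode: str = "unclassified"
    params: dict = field(default_factory=dict)


def _sustained_start(condition: np.ndarray, m: int) -> int | None:
    """First index where ``condition`` holds for ``m`` consecutive entries."""
    if m <= 0:
        raise ValueError("persistence m must be positive")
    cond = np.asarray(condition, dtype=bool)
    if len(cond) < m:
        return None
    window = np.convolve(cond.astype(int), np.ones(m, dtype=int), mode="valid")
    hits = np.flatnonzero(window == m)
    return int(hits[0]) if hits.size else None


def _refine_changepoint(
    r: np.ndarray, t_star: int, window: int, hi_cap: int | None = None
) -> int:
    """Least-squares single changepoint on radial increments near ``t_star``.

    Fits a two-segment piecewise-constant model to the increments of ``r``
    over ``[t_star - window, t_star + 2 * window)`` and returns the split
    minimising the residual sum of squares.  Ties (e.g. a perfectly
    uniform ramp) fall back to ``t_star``.  ``hi_cap`` bounds the window
    (retroactivity: frames after the peripheral reach must not matter).
    """
    lo = max(t_star - window, 0)
    hi = min(t_star + 2 * window, len(r) - 1)
    if hi_cap is not None:
        hi = min(hi, hi_cap)
    inc = np.diff(r[lo : hi + 1])
    if len(inc) < 2:
        return t_star
    best_split, best_sse = None, None
    for split in range(1, len(inc)):
        a, b = inc[:split], inc[split:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_split = sse, split
    total_sse = ((inc - inc.mean()) ** 2).sum()
    if best_split is None or total_sse - best_sse <= 1e-12:
        return t_star
    return lo + best_split


def detect_phase2_entry(
    r_dc: np.ndarray,
    apical_radius_um: float,
    window_w: int = 9,
    q: float = 0.6,
    dr_min_um: float = 1.0,
    rho: float = 0.6,
    refine: bool = True,
) -> tuple[int | None, str | None]:
    """Detect the Phase-II entry frame from the DC radial series.

    Returns ``(frame, reason)``; ``reason`` names the failed condition
    when no frame qualifies.  Defaults: ``W`` = 9 frames (1.5 hr at 10-min
    frames), ``q`` = 0.6, ``dr_min`` = 1.0 um, ``rho`` = 0.6.
    """
    r = np.asarray(r_dc, dtype=float)
    n = len(r)
    if n < window_w + 1:
        raise ValueError(f"need at least W + 1 = {window_w + 1} frames")
    reach = r >= rho * apical_radius_um
    if not reach.any():
        return None, "radius never reaches rho * R"
    inc = np.diff(r)
    gained = False
    for t in range(0, n - window_w):
        gain = r[t + window_w] - r[t]
        if gain < dr_min_um:
            continue
        gained = True
        frac_pos = np.mean(inc[t : t + window_w] > 0)
        if frac_pos < q:
            continue
        if not reach[t:].any():
            continue
        if refine:
            first_reach = int(np.flatnonzero(reach)[0])
            entry = _refine_changepoint(r, t, window_w, hi_cap=max(first_reach, t))
        else:
            entry = t
        return entry, None
    if not gained:
        return None, f"no window gains dr_min = {dr_min_um} um"
    return None, "no window is consistently outward"


def detect_late_phase2(
    r_mc: np.ndarray,
    r_dc: np.ndarray,
    apical_radius_um: float,
    rho: float = 0.6,
    persistence_m: int = 3,
) -> int | None:
    """Earliest frame from which both centrioles stay peripheral."""
    r_mc = np.asarray(r_mc, dtype=float)
    r_dc = np.asarray(r_dc, dtype=float)
    if len(r_mc) != len(r_dc):
        raise ValueError("radial series length mismatch")
    both = (r_mc >= rho * apical_radius_um) & (r_dc >= rho * apical_radius_um)
    return _sustained_start(both, persistence_m)


def classify_mode(
    s_dc: np.ndarray, delta_um: float = 1.0, persistence_m: int = 6
) -> str:
    """Classify the DC trajectory as ``direct``, ``reversal`` or neither.

    The signed coordinate ``s_dc`` is positive toward the original
    periphery-ward (lateral) target.  ``reversal``: a sustained excursion
    beyond ``+delta`` followed by a sustained excursion beyond ``-delta``.
    ``direct``: a sustained ``-delta`` excursion with no prior sustained
    ``+delta`` excursion.  Anything else is ``unclassified``.
    """
    s = np.asarray(s_dc, dtype=float)
    pos_start = _sustained_start(s >= delta_um, persistence_m)
    neg_start = _sustained_start(s <= -delta_um, persistence_m)
    if neg_start is None:
        return "unclassified"
    if pos_start is not None and pos_start < neg_start:
        # require the medial excursion to begin after the lateral one ended
        later_neg = _sustained_start(
            (np.arange(len(s)) > pos_start) & (s <= -delta_um), persistence_m
        )
        return "reversal" if later_neg is not None else "unclassified"
    return "direct"


def detect_reporter_onset(
    intensity: np.ndarray,
    background_window: int | np.ndarray = 6,
    k: float = 3.0,
    persistence_m: int = 3,
) -> int | None:
    """First sustained excursion of the reporter above background.

    Background statistics come either from the first ``background_window``
    frames of the series itself or from an explicitly supplied background
    series (e.g. a neighbouring region).
    """
    y = np.asarray(intensity, dtype=float)
    if len(y) < persistence_m:
        raise ValueError("series shorter than the persistence window")
    if np.isscalar(background_window):
        bg = y[: int(background_window)]
    else:
        bg = np.asarray(background_window, dtype=float)
    mu, sd = float(np.mean(bg)), float(np.std(bg))
    return _sustained_start(y > mu + k * sd, persistence_m)


def perturbation_events(
    s_dc: np.ndarray | None = None,
    r_dc: np.ndarray | None = None,
    reporter: np.ndarray | None = None,
    apical_radius_um: float | None = None,
    drug_window: tuple[int, int] | None = None,
    frame_interval: float = 10.0,
    delta_um: float = 1.0,
    persistence_m: int = 6,
    rho_loss: float = 0.6,
    onset_k: float = 3.0,
    onset_persistence: int = 3,
    background_window: int | np.ndarray = 6,
    loss_persistence: int = 3,
) -> EventRecord:
    """Assemble the per-cell event record for perturbation experiments.

    Reversal latency is ``(reversal - onset) * frame_interval`` (in hours);
    peripheral loss is the first sustained sub-threshold DC radius within
    or after the drug window, with the delay in minutes from drug start.
    Missing prerequisites leave the corresponding fields ``None``.
    """
    rec = EventRecord(
        drug_window=drug_window,
        params={
            "delta_um": delta_um,
            "persistence_m": persistence_m,
            "rho_loss": rho_loss,
            "onset_k": onset_k,
            "onset_persistence": onset_persistence,
        },
    )
    if reporter is not None:
        rec.reporter_onset_frame = detect_reporter_onset(
            reporter, background_window, onset_k, onset_persistence
        )
    if s_dc is not None:
        s = np.asarray(s_dc, dtype=float)
        rec.mode = classify_mode(s, delta_um, persistence_m)
        pos_start = _sustained_start(s >= delta_um, persistence_m)
        if pos_start is not None:
            after = (np.arange(len(s)) > pos_start) & (s <= -delta_um)
            rec.reversal_frame = _sustained_start(after, persistence_m)
        if rec.reversal_frame is not None and rec.reporter_onset_frame is not None:
            rec.latency_hr = (
                (rec.reversal_frame - rec.reporter_onset_frame)
                * frame_interval
                / 60.0
            )
    if r_dc is not None and drug_window is not None:
        if apical_radius_um is None:
            raise ValueError("peripheral loss needs the apical radius")
        r = np.asarray(r_dc, dtype=float)
        start = drug_window[0]
        below = (np.arange(len(r)) >= start) & (r < rho_loss * apical_radius_um)
        loss = _sustained_start(below, loss_persistence)
        if loss is not None:
            rec.peripheral_loss_frame = loss
            rec.loss_delay_min = (loss - start) * frame_interval
    return rec


def fraction_within(
    loss_delays_min: Sequence[float | None], cutoff_min: float
) -> tuple[int, int, float]:
    """Cohort helper: fraction of cells losing peripheral position in time.

    ``None`` entries (no loss observed) count toward the denominator.
    Returns ``(count, total, fraction)``.
    """
    delays = list(loss_delays_min)
    total = len(delays)
    count = sum(1 for d in delays if d is not None and d <= cutoff_min)
    return count, total, (count / total if total else float("nan"))
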