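# Methods

This note documents the models, parameter choices and numerical
conventions behind `centritrack`, and what the synthetic-data validation
does and does not establish about real recordings.

## Coordinate and timing conventions

Physical coordinates are micrometres with the origin at the stack corner;
`z` increases apically. Voxel indices are 0-based and a voxel's physical
position is `index × calibration` (voxel centres). Frames are 0-based and
all intervals are half-open `[start, end)`. Default calibration: 0.216 µm
x–y pixels, 0.5 µm z step, 10 min per frame. "First frame where" rules
always return the earliest index; sustained-condition windows require `m`
consecutive frames.

## The two-centriole simulation

Each cell is simulated on an apical disk of radius `R` (default 4 µm)
with a discrete-time tethered random walk updated once per frame:

```
x(t+1) = x(t) + clamp(target(t) − x(t), v_regime) + η(t),   η ~ N(0, σ² I)
```

followed by truncation of the total x–y step at the per-centriole bound
(MC 0.5 µm/frame, DC 1.2 µm/frame). The deterministic part moves toward
the current regime target at most `v_regime` per frame; the bound makes
the observed per-frame speed limits structural rather than emergent. We
chose this capped-step form over an explicit Ornstein–Uhlenbeck
stiffness/diffusion parameterization because the speed bounds are the only
quantitative kinetic constraints available; an OU model would need
post-hoc truncation to respect them anyway. A `untethered` flag removes
the deterministic part, recovering free diffusion with
`D = σ²/(2Δt)` — the MSD of an untethered track matches `4Dτ` within 15%
at small lags, which is the calibration check for the noise scale.

Regimes:

- **Phase I** (frames `< phase2_entry_frame`, default 100): the MC's
  target is the cell centre (wander σ = 0.08 µm/axis/frame), the DC's
  target is the MC (σ = 0.22). This keeps the DC within ~0.3 R of the
  centre while its step distribution clearly dominates the MC's
  (95th percentiles ≈ 0.7 vs 0.27 µm/frame).
- **Phase II**: the DC's target jumps to `ρR` along the polarity axis
  (ρ = 0.85) and it travels at 0.4 µm/frame; after a 6-frame lag the MC
  follows at 0.25 µm/frame to an anchor 0.7 µm inside the DC's. The
  apical–basal gap between the centrioles (MC above DC) shrinks from
  1.0 µm (Phase I) to 0.3 µm (Phase II), with 0.12 µm jitter — so the
  planar separation grows while the axial separation falls, the printed
  direction of both effects.
- **Perturbations** (half-open windows): `emx2_switch` flips the polarity
  axis at its start frame; a flip at frame 0 yields a *direct* reversed
  trajectory, a flip after Phase-II progress yields a *reversal*
  (peripheral excursion, then crossing to the opposite side).
  `nocodazole` replaces both targets by the cell centre at a recall speed
  of 0.5 µm/frame (peripheral position is lost within a few frames,
  matching the tens-of-minutes recall seen experimentally) and amplifies
  DC wander ×1.5; washout restores the prior regime.
- An optional paired-recentering stage (both centrioles re-tethered at
  0.3 R, preserving their offset) models the late central shift; it is
  off by default because only some recordings reach it.

The cytoplasmic reporter is `background + rate × (t − onset)⁺` (linear
ramp, default 2 AU/frame over a 20 AU background with 4 AU measurement
noise); the generator records the analytic frame at which the noise-free
ramp crosses `background + 3σ` as the ground-truth "detectable onset".
Whole-cell drift is a per-frame velocity added to both centrioles and the
centre. Cohorts derive per-cell seeds from a master seed via
`SeedSequence.spawn`, so outputs are bit-reproducible; exact mode
assignment uses `round(n × fraction)` counts.

Ground-truth event frames are recorded from the realized trajectory with
the same physical definitions the detectors use (first frame both radii
≥ 0.6 R for late Phase II; first frame the signed DC coordinate crosses
−1 µm after an axis flip for reversal arrival), so detector validation
compares like with like without sharing code paths.

## Rendering

Channel 0: isotropic 3D Gaussian spots (σ = 1.5 px x–y, 1 plane z,
default 120 photons at peak) at the MC and DC positions. Channel 1: a
filled disk of radius `R` at the cell centre spanning three z planes,
scaled by the reporter ramp (dark before onset). Both channels sit on a
1-photon background and are corrupted by Poisson photon noise plus
1-photon-RMS Gaussian read noise, giving a peak spot SNR of roughly 10.
No PSF physics beyond the Gaussian approximation, no occlusion, no
stereocilia rendering.

## Drift correction

Stage drift is estimated between consecutive frames — x–y by 2D phase
correlation of maximum-intensity projections, z by phase correlation of
the axial intensity profile — with subvoxel refinement by correlation-peak
upsampling (default ×10), then accumulated to a reference frame.
Frame-to-frame chaining (rather than all-to-reference) is robust to the
slow morphological change of a developing explant. Estimation must run on
the **reporter channel**: the centriole channel's content moves
biologically by up to ~5 px/frame, which phase correlation cannot
distinguish from drift (measured ~0.7 voxel/pair error on spots vs
~0.1 voxel RMS total on the reporter disk). Correction applies the inverse
translation (exact for integer shifts, linear interpolation otherwise)
with zero-fill and a validity mask, since downstream masking must know
which voxels were invented. Empty or constant frames get zero shift and a
low-confidence flag.

## Masking, detection, linking, roles

Cells are segmented per frame on the reporter projection (Otsu threshold
by default); a frame counts as signal only if the mean suprathreshold
intensity clears the projection's robust noise band
(median + 5 × 1.4826 MAD), so pre-onset frames yield no mask and the first
mask frame tracks reporter onset. Identities persist by maximum pixel
overlap, bridging dropouts of up to 5 frames. The centriole channel is
zeroed outside cell masks dilated by 0.5 µm.

Spots are maxima of a scale-matched Laplacian-of-Gaussian response above
median + 5 × 1.4826 MAD (statistics over signal-carrying voxels, so masked
regions do not deflate the noise estimate), refined by an
intensity-weighted 3×3 centroid in x–y and a 3-plane parabolic fit in z.
A detection whose principal-axis width exceeds 1.07 × the nominal spot
width is flagged as a possible merge of two unresolved spots; the factor
sits between the measured single-spot (≤ 1.57 px) and 0.4-µm-pair
(≥ 1.66 px) width distributions at the default rendering scale.

Linking assumes at most one MC and one DC per cell (hair cells are
post-mitotic): frame-to-frame assignment enumerates both pairings of ≤ 2
spots and keeps the minimum-summed-displacement one under a 2.5 µm/frame
gate (scaled by the gap length when closing gaps of up to 2 frames, which
are filled by linear interpolation and flagged). When the pair is
unresolvable — common in Phase I, where the separation is often below
2σ — the single merged detection is shared by both tracks and flagged like
an interpolated position, so speed statistics exclude it; without this,
merged runs longer than the gap limit would fragment the tracks. The MC is
the track with the greater mean z over the common frames (mean rather than
per-frame apicality, because the z gap fluctuates); ties below 0.1 µm fall
back to the lower x–y step variance with an ambiguity flag.

## Trajectory quantities

Distances: `d_xy` planar Euclidean, `d_z = |Δz|` on registered (not
centre-relative) z, since the cell centre is a 2D apical quantity. Speeds:
x–y only, per frame, on centre-relative coordinates, excluding
gap-interpolated frames (interpolation deflates step sizes); z is excluded
from speed by definition. MSD: time-averaged over all start frames; α from
log-log least squares over lags 1–10. The polarity axis defaults to the
unit vector from the mean centre to the DC's mean position over the final
3 h of the recording, with an explicit override for tissue anatomy or
ground truth; before the first reporter mask the MC position is the
centre proxy. Phase summaries optionally apply the lateral-cell
convention of averaging Phase I over only the last 30 frames before
Phase-II entry (earlier frames may predate hair-cell identity); medial
cells use all Phase-I frames.

## Event detectors

All detectors are deterministic given inputs and parameters, and the
parameters used are recorded in the outputs.

- **Phase-II entry** (W = 9 frames, q = 0.6, Δr_min = 1.0 µm, ρ = 0.6):
  the earliest frame `t*` whose following W-frame window gains ≥ Δr_min of
  DC radius with ≥ q positive increments, provided the radius later
  reaches ρR. Because a window straddling the true kink already satisfies
  these conditions, the earliest qualifying `t*` is biased a few frames
  early; a least-squares single-changepoint fit to the radial increments
  over `[t* − W, t* + 2W)` pins the entry (ties, e.g. a uniform ramp, fall
  back to `t*`; `refine=False` gives the bare rule). The refinement window
  is capped at the first ρR-reach frame so the decision is retroactive:
  appending frames after the reach cannot change it. The window-based
  operationalisation is this package's definition of "consistently moving
  toward the periphery"; the qualitative published rule fixes no numbers.
- **Late Phase II**: both radii ≥ ρR for m = 3 consecutive frames. ρ = 0.6
  detects the simulated peripheral tether (at 0.85 R) with margin.
- **Mode** (δ = 1 µm, m = 6 frames): *reversal* = sustained `s ≥ +δ` then
  a later sustained `s ≤ −δ`; *direct* = sustained `s ≤ −δ` without a
  prior sustained positive excursion; otherwise *unclassified*. On series
  sustaining both excursions the classifier is antisymmetric under axis
  flip.
- **Reporter onset** (k = 3, m = 3): first sustained excursion above
  `µ_b + kσ_b`, with background statistics from the first 6 frames by
  default or an explicit background series. On noisy ramps the sustained
  rule detects slightly after the noise-free crossing (median +1 frame at
  the generator's default noise).
- **Perturbation events**: reversal frame = start of the sustained
  negative excursion; latency = (reversal − onset) × Δt in hours;
  peripheral loss = first sustained `r_DC < ρ_loss R` at or after drug
  start, with the delay in minutes; a cohort helper reports the fraction
  of cells with loss delay under a cutoff.

## Statistics and reporting

Student's pooled-variance t-test is the default two-sample test (Welch
exposed as a variant); identical zero-variance samples return p = 1 with a
degeneracy flag. The 2×2 chi-square uses the closed form
`N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))` with df = 1 and **no** continuity
correction: on the contingency reconstructed from the two ectopic-Emx2
driver cohorts — (9, 6 | 6, 33) from n = 15 at 60/40% and n = 39 at
15.4/84.6% — the uncorrected form gives p = 0.0010 at the printed
precision (χ² ≈ 10.75) while the Yates-corrected form gives ≈ 0.003, so
the uncorrected test is what the published value corresponds to; a Fisher
exact p is attached alongside for small tables. One-way ANOVA is
`F = MS_between/MS_within`. Percentages print to one decimal with
round-half-up (17/28 → 60.7). The report computes phase contrasts both
per-frame and on per-cell means and labels them, since frame-wise testing
treats autocorrelated frames as independent (pseudo-replication). Reports
regenerate bit-identically from the same inputs and seeds. No
multiple-testing correction is applied.

## Problem sizes used in validation

Track-level validation uses 50-cell, 250-frame cohorts (about 42 h of
recording at 10-min frames, matching the published recording lengths);
image-level validation uses 30-frame, 12×96×96-voxel renderings for drift
recovery and the end-to-end tracking check, and 20 two-spot frames for
localization. These sizes give stable statistics while keeping the full
suite and the acceptance script fast; all are set in the tests and in
`scripts/acceptance.py` and scale up without code changes.

## What synthetic validation shows — and does not

Against generator ground truth, the pipeline recovers Phase-II entry
within ±3 frames in ≥ 90% of cells, assigns MC/DC roles and trajectory
modes with ≥ 95% accuracy, recovers injected drift within 0.5 voxel RMS
and localizes well-separated spots with ≤ 0.5 voxel median error at peak
SNR ≈ 10. These numbers certify the estimators under the generator's
assumptions: isotropic Gaussian spots, a single circular cell, linear
reporter kinetics, piecewise-stationary dynamics with scheduled regime
switches, and translational drift only. Real recordings add crowded
multi-cell fields, irregular cell shapes, z-dependent aberrations,
photobleaching and focus drift, none of which are modelled; recovery rates
on real data should be expected to be lower, and the published per-cell
p-values cannot be reproduced without the original coordinate tables. The
Phase-I confinement radius and tether strength are free parameters of the
generator, not measured quantities.
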