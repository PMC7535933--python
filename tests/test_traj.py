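import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centritrack import (
    CellFrameSeries,
    CentrioleTrack,
    CellMaskSeries,
    build_center_series,
    frame_speeds,
    msd_curve,
    pair_distances,
    phase_summary,
    radial_series,
)
from centritrack.pipeline import centers_from_truth


def _track(xyz, role="DC", frames=None, interp=None):
    xyz = np.asarray(xyz, dtype=float)
    frames = np.arange(len(xyz)) if frames is None else frames
    return CentrioleTrack(0, 0, role, frames, xyz, interpolated=interp)


def _centers(center_xy, axis=(1.0, 0.0), R=4.0):
    center_xy = np.asarray(center_xy, dtype=float)
    n = len(center_xy)
    return CellFrameSeries(
        frames=np.arange(n),
        center_xy=center_xy,
        mode=np.array(["mask_centroid"] * n),
        apical_radius_um=R,
        polarity_axis=np.asarray(axis, dtype=float),
        proxy_switch_frame=None,
    )


class TestPairDistances:
    def test_coincident_points_zero(self):
        a = _track([[1, 2, 3]], role="MC")
        b = _track([[1, 2, 3]])
        d = pair_distances(a, b)
        assert d.d_xy[0] == 0 and d.d_z[0] == 0

    def test_hand_computed_3_4_5(self):
        a = _track([[0, 0, 0]], role="MC")
        b = _track([[3, 4, 1]])
        d = pair_distances(a, b)
        assert d.d_xy[0] == pytest.approx(5.0)
        assert d.d_z[0] == pytest.approx(1.0)

    def test_no_overlap_raises(self):
        a = _track([[0, 0, 0]], role="MC", frames=np.array([0]))
        b = _track([[0, 0, 0]], frames=np.array([5]))
        with pytest.raises(ValueError):
            pair_distances(a, b)

    def test_cohort_phase_directions(self, default_cohort):
        """Phase II x-y distance larger, z distance smaller than Phase I."""
        d1_xy, d2_xy, d1_z, d2_z = [], [], [], []
        for truth in default_cohort:
            d = pair_distances(truth.mc_track(), truth.dc_track())
            e = truth.phase2_entry_frame
            d1_xy.append(d.d_xy[:e].mean())
            d2_xy.append(d.d_xy[e:].mean())
            d1_z.append(d.d_z[:e].mean())
            d2_z.append(d.d_z[e:].mean())
        assert np.mean(d2_xy) > np.mean(d1_xy)
        assert np.mean(d2_z) < np.mean(d1_z)


class TestFrameSpeeds:
    def test_static_relative_track_zero_speed(self):
        tr = _track(np.tile([1.0, 2.0, 0.0], (5, 1)))
        sp = frame_speeds(tr, _centers(np.zeros((5, 2))))
        np.testing.assert_allclose(sp.speeds, 0.0)

    def test_hand_computed_3_4_step(self):
        xy = np.cumsum(np.tile([0.3, 0.4], (6, 1)), axis=0)
        tr = _track(np.c_[xy, np.zeros(6)])
        sp = frame_speeds(tr, _centers(np.zeros((6, 2))))
        np.testing.assert_allclose(sp.speeds, 0.5)

    def test_drift_removed_by_center_reference(self, default_cohort):
        """MC detrended speed stays within the 0.5 um/frame bound even
        with whole-cell drift injected."""
        from centritrack import inject_track_drift

        truth = default_cohort[0]
        drift = np.outer(np.arange(truth.n_frames), [0.4, -0.3])
        drifted = inject_track_drift(truth, drift)
        sp = frame_speeds(drifted.mc_track(), centers_from_truth(drifted))
        assert sp.speeds.max() <= 0.5 + 1e-9

    def test_interpolated_frames_flagged_invalid(self):
        interp = np.zeros(5, bool)
        interp[2] = True
        tr = _track(np.zeros((5, 3)), interp=interp)
        sp = frame_speeds(tr, _centers(np.zeros((5, 2))))
        assert not sp.valid[1] and not sp.valid[2]
        assert sp.valid[0] and sp.valid[3]

    def test_single_frame_raises(self):
        tr = _track([[0, 0, 0]])
        with pytest.raises(ValueError):
            frame_speeds(tr, _centers(np.zeros((1, 2))))


class TestMsdCurve:
    def test_static_track_zero(self):
        m = msd_curve(np.zeros((20, 2)))
        np.testing.assert_allclose(m.msd_um2, 0.0)

    def test_ballistic_exponent_two(self):
        """Constant-velocity track: MSD = v^2 tau^2, alpha = 2 +- 0.05."""
        v = 0.3
        xy = np.cumsum(np.tile(v / np.sqrt(2), (60, 2)), axis=0)
        m = msd_curve(xy, max_lag=20)
        assert m.alpha == pytest.approx(2.0, abs=0.05)
        taus = np.arange(21)
        np.testing.assert_allclose(m.msd_um2, v**2 * taus.astype(float) ** 2, rtol=1e-9)

    def test_brownian_exponent_near_one(self):
        rng = np.random.default_rng(10)
        D, dt = 0.002, 10.0
        xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (1000, 2)), axis=0)
        m = msd_curve(xy, max_lag=20, frame_interval=dt)
        assert 0.85 <= m.alpha <= 1.15
        np.testing.assert_allclose(m.msd_um2[1], 4 * D * dt, rtol=0.15)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.normal(0, 0.3, (20, 2)), axis=0)
        m = msd_curve(xy, max_lag=10)
        for tau in range(1, 11):
            brute = np.mean(
                [np.sum((xy[i + tau] - xy[i]) ** 2) for i in range(20 - tau)]
            )
            assert m.msd_um2[tau] == pytest.approx(brute)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            msd_curve(np.zeros((5, 2)))


class TestRadialSeries:
    def test_point_at_center(self):
        tr = _track([[1.0, 1.0, 0.0]])
        _, r, s = radial_series(tr, _centers([[1.0, 1.0]]))
        assert r[0] == 0 and s[0] == 0

    def test_signed_projection(self):
        tr = _track([[2.0, 0.0, 0.0], [-2.0, 0.0, 0.0]], frames=np.array([0, 1]))
        _, r, s = radial_series(tr, _centers(np.zeros((2, 2))))
        np.testing.assert_allclose(s, [2.0, -2.0])
        np.testing.assert_allclose(r, [2.0, 2.0])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        tr = _track(np.c_[xy, np.zeros(10)])
        tr_rot = _track(np.c_[xy @ rot.T, np.zeros(10)])
        _, r0, s0 = radial_series(tr, _centers(np.zeros((10, 2)), axis=(1, 0)))
        axis_rot = rot @ np.array([1.0, 0.0])
        _, r1, s1 = radial_series(tr_rot, _centers(np.zeros((10, 2)), axis=axis_rot))
        np.testing.assert_allclose(r0, r1, atol=1e-12)
        np.testing.assert_allclose(s0, s1, atol=1e-12)


class TestBuildCenterSeries:
    def _masks(self, frames, centroid=(5.0, 5.0), radius=4.0):
        frames = np.asarray(frames, dtype=int)
        return CellMaskSeries(
            cell_id=0,
            frames=frames,
            masks=[np.ones((4, 4), bool)] * len(frames),
            centroids_um=np.tile(centroid, (len(frames), 1)).astype(float),
            radii_um=np.full(len(frames), radius),
        )

    def test_masks_everywhere_use_centroid_mode(self):
        mc = _track(np.zeros((6, 3)), role="MC")
        centers = build_center_series(
            self._masks(np.arange(6)), mc, polarity_axis=(1, 0)
        )
        assert (centers.mode == "mask_centroid").all()
        assert centers.proxy_switch_frame == 0

    def test_mc_proxy_before_first_mask(self):
        """Before reporter onset the MC stands in for the cell centre."""
        mc = _track(np.tile([1.0, 2.0, 0.0], (8, 1)), role="MC")
        centers = build_center_series(
            self._masks(np.arange(5, 8)), mc, polarity_axis=(1, 0)
        )
        assert centers.proxy_switch_frame == 5
        assert (centers.mode[:5] == "mc_proxy").all()
        assert (centers.mode[5:] == "mask_centroid").all()
        np.testing.assert_allclose(centers.center_xy[:5], [[1.0, 2.0]] * 5)

    def test_axis_estimated_from_late_dc_position(self):
        mc = _track(np.zeros((20, 3)), role="MC")
        dc_xy = np.c_[np.linspace(0, 3, 20), np.zeros(20), np.zeros(20)]
        dc = _track(dc_xy)
        centers = build_center_series(self._masks(np.arange(20), centroid=(0, 0)), mc, dc_track=dc)
        np.testing.assert_allclose(centers.polarity_axis, [1.0, 0.0], atol=1e-9)


class TestPhaseSummary:
    def _series(self):
        from centritrack.traj import DistanceSeries, SpeedSeries

        frames = np.arange(60)
        d = DistanceSeries(
            frames=frames,
            d_xy=np.where(frames < 50, 0.5, 2.0),
            d_z=np.where(frames < 50, 1.0, 0.2),
        )
        sp = SpeedSeries(
            frames=frames[:-1],
            speeds=np.full(59, 0.3),
            valid=np.ones(59, bool),
            role="DC",
        )
        return d, {"DC": sp}

    def test_single_phase_leaves_phase2_empty(self):
        d, sp = self._series()
        out = phase_summary(d, sp, phase2_entry_frame=None)
        row2 = out[out.phase == "II"].iloc[0]
        assert np.isnan(row2.mean_d_xy)

    def test_lat_rule_uses_last_30_frames(self):
        """Lateral convention: Phase-I mean over frames entry-30..entry-1."""
        from centritrack.traj import DistanceSeries

        frames = np.arange(60)
        d = DistanceSeries(
            frames=frames, d_xy=frames.astype(float), d_z=np.zeros(60)
        )
        _, sp = self._series()
        out = phase_summary(d, sp, phase2_entry_frame=50, lat_rule=True)
        row1 = out[out.phase == "I"].iloc[0]
        assert row1.n_frames == 30
        assert row1.mean_d_xy == pytest.approx(np.mean(np.arange(20, 50)))

    def test_hand_built_means(self):
        d, sp = self._series()
        out = phase_summary(d, sp, phase2_entry_frame=50)
        row1 = out[out.phase == "I"].iloc[0]
        row2 = out[out.phase == "II"].iloc[0]
        assert row1.mean_d_xy == pytest.approx(0.5)
        assert row2.mean_d_xy == pytest.approx(2.0)
        assert row2.mean_d_z == pytest.approx(0.2)
        assert row1.mean_speed_dc == pytest.approx(0.3)


class TestTranslationInvariance:
    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_common_offset_changes_nothing(self, ox, oy):
        """Adding one offset to track and centres leaves all outputs fixed."""
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(12, 2))
        centers_xy = rng.normal(size=(12, 2))
        off = np.array([ox, oy])
        tr0 = _track(np.c_[xy, np.zeros(12)])
        tr1 = _track(np.c_[xy + off, np.zeros(12)])
        c0 = _centers(centers_xy)
        c1 = _centers(centers_xy + off)
        np.testing.assert_allclose(
            frame_speeds(tr0, c0).speeds, frame_speeds(tr1, c1).speeds, atol=1e-9
        )
        _, r0, s0 = radial_series(tr0, c0)
        _, r1, s1 = radial_series(tr1, c1)
        np.testing.assert_allclose(r0, r1, atol=1e-9)
        np.testing.assert_allclose(s0, s1, atol=1e-9)

    def test_dc_faster_than_mc_in_both_phases(self, default_cohort):
        """Mean DC speed exceeds mean MC speed in Phase I and Phase II."""
        mc1, mc2, dc1, dc2 = [], [], [], []
        for truth in default_cohort:
            centers = centers_from_truth(truth)
            sp_mc = frame_speeds(truth.mc_track(), centers)
            sp_dc = frame_speeds(truth.dc_track(), centers)
            e = truth.phase2_entry_frame
            mc1.append(sp_mc.speeds[sp_mc.frames < e].mean())
            mc2.append(sp_mc.speeds[sp_mc.frames >= e].mean())
            dc1.append(sp_dc.speeds[sp_dc.frames < e].mean())
            dc2.append(sp_dc.speeds[sp_dc.frames >= e].mean())
        assert np.mean(dc1) > np.mean(mc1)
        assert np.mean(dc2) > np.mean(mc2)
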