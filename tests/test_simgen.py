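import numpy as np
import pytest

from centritrack import (
    AcquisitionGeometry,
    NoiseModel,
    Perturbation,
    SimulationParams,
    export_ground_truth,
    inject_drift,
    read_tracks_csv,
    render_image_series,
    simulate_cell,
    simulate_cohort,
)
from centritrack.simgen import render_frame
from centritrack.traj import msd_curve


def _steps_xy(xyz: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(xyz[:, :2], axis=0), axis=1)


class TestSimulateCell:
    def test_frozen_dynamics_are_stationary(self):
        p = SimulationParams(
            sigma_mc=0.0,
            sigma_dc=0.0,
            sigma_phase2=0.0,
            sigma_z=0.0,
            drift_speed_phase2=0.0,
            mc_follow_speed=0.0,
            max_step_mc=0.0,
            max_step_dc=0.0,
            cell_drift_velocity=(0.0, 0.0),
        )
        t = simulate_cell(p, seed=1)
        assert np.allclose(t.mc[:, :2], t.mc[0, :2])
        assert np.allclose(t.dc[:, :2], t.dc[0, :2])

    def test_dc_steps_dominate_mc_steps(self):
        t = simulate_cell(SimulationParams(), seed=7)
        s_mc, s_dc = _steps_xy(t.mc), _steps_xy(t.dc)
        assert np.percentile(s_dc, 95) > np.percentile(s_mc, 95)

    def test_per_frame_step_bounds(self):
        """DC steps stay within ~1.2 um and MC within 0.5 um per frame."""
        for seed in (7, 8, 9):
            t = simulate_cell(SimulationParams(), seed=seed)
            assert _steps_xy(t.mc).max() <= 0.5 + 1e-9
            assert _steps_xy(t.dc).max() <= 1.2 + 1e-9

    def test_mc_more_apical_and_phase1_confined(self):
        p = SimulationParams()
        t = simulate_cell(p, seed=2)
        assert t.mc[:, 2].mean() > t.dc[:, 2].mean()
        entry = t.phase2_entry_frame
        r_dc = np.linalg.norm(t.dc[:entry, :2] - t.cell_center[:entry], axis=1)
        assert r_dc.max() < 0.3 * p.apical_radius_R

    def test_phase_distance_directions(self):
        """x-y separation grows and z separation shrinks from I to II."""
        t = simulate_cell(SimulationParams(), seed=5)
        e = t.phase2_entry_frame
        d_xy = np.linalg.norm(t.mc[:, :2] - t.dc[:, :2], axis=1)
        d_z = np.abs(t.mc[:, 2] - t.dc[:, 2])
        assert d_xy[e:].mean() > d_xy[:e].mean()
        assert d_z[e:].mean() < d_z[:e].mean()

    def test_emx2_switch_sends_dc_medial(self):
        p = SimulationParams()
        t = simulate_cell(p, [Perturbation("emx2_switch", start=0)], seed=3)
        s = t.signed_dc()
        assert s[-1] < -0.5 * p.peripheral_fraction * p.apical_radius_R
        assert t.mode_label == "direct"

    def test_nocodazole_recalls_dc_to_center(self):
        """DC radius drops below 0.6 R inside the drug window."""
        p = SimulationParams(phase2_entry_frame=20, n_frames=120)
        drug = Perturbation("nocodazole", start=80, end=110)
        t = simulate_cell(p, [drug], seed=4)
        r_dc = np.linalg.norm(t.dc[:, :2] - t.cell_center, axis=1)
        assert r_dc[85:110].max() < 0.6 * p.apical_radius_R
        assert t.peripheral_loss_frame is not None
        assert t.peripheral_loss_frame >= drug.start
        # washout: directed migration resumes
        assert r_dc[-1] > 0.6 * p.apical_radius_R

    def test_perturbation_window_validation(self):
        with pytest.raises(ValueError):
            simulate_cell(
                SimulationParams(n_frames=50),
                [Perturbation("nocodazole", start=40, end=60)],
                seed=0,
            )

    def test_untethered_msd_matches_free_diffusion(self):
        """With tethering off, x-y MSD follows 4 D tau at small lags."""
        p = SimulationParams(
            n_frames=1200,
            phase2_entry_frame=10**6,
            untethered=True,
            cell_drift_velocity=(0.0, 0.0),
        )
        t = simulate_cell(p, seed=42)
        rel = t.dc[:, :2] - t.cell_center
        curve = msd_curve(rel, max_lag=5, frame_interval=p.frame_interval)
        D = p.sigma_dc**2 / (2 * p.frame_interval)
        expected = 4 * D * curve.lag_min[1:]
        np.testing.assert_allclose(curve.msd_um2[1:], expected, rtol=0.15)

    @pytest.mark.parametrize("bad", [{"apical_radius_R": np.nan}, {"sigma_dc": -1.0}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationParams(**bad)


class TestSimulateCohort:
    def test_empty_cohort(self):
        assert simulate_cohort(SimulationParams(), 0, seed=1) == []

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationParams(), -1, seed=1)

    def test_exact_mode_assignment_gfi1_fractions(self):
        """n = 39 at 84.6% reversal yields exactly 33 reversal, 6 direct."""
        cohort = simulate_cohort(
            SimulationParams(),
            39,
            mode_fractions={"direct": 0.154, "reversal": 0.846},
            seed=2,
        )
        modes = [t.mode_label for t in cohort]
        assert modes.count("reversal") == 33
        assert modes.count("direct") == 6

    def test_same_seed_reproduces_cohort_bitwise(self):
        kw = dict(mode_fractions={"direct": 0.5, "reversal": 0.5}, seed=9)
        a = simulate_cohort(SimulationParams(), 6, **kw)
        b = simulate_cohort(SimulationParams(), 6, **kw)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.mc, y.mc)
            np.testing.assert_array_equal(x.dc, y.dc)
            assert x.mode_label == y.mode_label


class TestRendering:
    def test_blank_without_spots_or_noise(self):
        geom = AcquisitionGeometry(stack_shape=(6, 32, 32), n_frames=1)
        vol = render_frame([], geom)
        assert np.all(vol == 0)

    def test_rendered_centroid_matches_position(self):
        """Intensity-weighted centroid of a noiseless spot ~ its position."""
        geom = AcquisitionGeometry(stack_shape=(10, 48, 48), n_frames=1)
        pos = np.array([20.3 * 0.216, 23.7 * 0.216, 2.6])
        vol = render_frame([pos], geom)
        zz, yy, xx = np.mgrid[:10, :48, :48]
        w = vol / vol.sum()
        centroid_vox = np.array([(w * a).sum() for a in (zz, yy, xx)])
        pos_vox = np.array([pos[2] / 0.5, pos[1] / 0.216, pos[0] / 0.216])
        assert np.all(np.abs(centroid_vox - pos_vox) < 0.25)

    def test_spot_outside_volume_names_error(self):
        geom = AcquisitionGeometry(stack_shape=(6, 32, 32), n_frames=1)
        with pytest.raises(ValueError, match="outside"):
            render_frame([np.array([100.0, 0.0, 0.0])], geom)

    def test_metadata_carries_calibration(self, rendered_cell):
        _, series, meta = rendered_cell
        assert meta["z_step_um"] == pytest.approx(0.5)
        assert meta["frame_interval_min"] == pytest.approx(10.0)
        assert meta["axes"] == "TCZYX"
        assert series.shape[1] == 2

    def test_reporter_channel_dark_before_onset(self):
        p = SimulationParams(n_frames=20, reporter_onset_frame=10)
        geom = AcquisitionGeometry(stack_shape=(8, 48, 48), n_frames=20)
        truth = simulate_cell(p, seed=6)
        series, _ = render_image_series(
            truth, geom, noise=NoiseModel(enabled=False), seed=0
        )
        bg = NoiseModel().background_photons
        assert np.all(series[:10, 1] == bg)
        assert series[-1, 1].max() > bg


class TestInjectDrift:
    def test_zero_drift_identity(self, rendered_cell):
        _, series, _ = rendered_cell
        single = series[:5, 0]
        out, true, flag = inject_drift(single, np.zeros((5, 3)))
        np.testing.assert_array_equal(out, single)
        assert not flag

    def test_constant_integer_drift_accumulates(self):
        """(1 px, 0) per frame for 10 frames puts frame 9 at (9, 0) px."""
        series = np.zeros((10, 2, 16, 16))
        series[:, :, 2, 2] = 1.0
        shifts = np.outer(np.arange(10), [0.0, 0.0, 1.0])
        out, true, _ = inject_drift(series, shifts)
        np.testing.assert_array_equal(true[9], [0, 0, 9])
        assert out[9][1, 2, 11] == 1.0
        assert out[9][1, 2, 2] == 0.0

    def test_non_finite_shift_rejected(self):
        with pytest.raises(ValueError):
            inject_drift(np.zeros((2, 4, 4, 4)), np.array([[0, 0, 0], [np.nan, 0, 0]]))


class TestExportGroundTruth:
    def test_roundtrip_through_reader(self, tmp_path):
        """Exported CSV re-imported via the track reader matches exactly."""
        truth = simulate_cell(SimulationParams(n_frames=3), seed=1)
        paths = export_ground_truth(truth, tmp_path)
        back = read_tracks_csv(paths["tracks"])
        assert {t.role for t in back} == {"MC", "DC"}
        mc = next(t for t in back if t.role == "MC")
        np.testing.assert_allclose(mc.xyz, truth.mc)

    def test_cohort_export_counts(self, tmp_path):
        cohort = simulate_cohort(SimulationParams(n_frames=3), 5, seed=3)
        paths = export_ground_truth(cohort, tmp_path)
        back = read_tracks_csv(paths["tracks"])
        assert len(back) == 10
        assert len({t.cell_id for t in back}) == 5
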