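import pytest

from centritrack import (
    AcquisitionGeometry,
    SimulationParams,
    render_image_series,
    simulate_cell,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def small_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(stack_shape=(12, 96, 96), n_frames=30)


@pytest.fixture(scope="session")
def default_cohort():
    """50-cell track-level cohort with a 40/60 direct/reversal split."""
    params = SimulationParams(reporter_onset_frame=54)
    return simulate_cohort(
        params,
        50,
        mode_fractions={"direct": 0.4, "reversal": 0.6},
        seed=11,
    )


@pytest.fixture(scope="session")
def rendered_cell(small_geometry):
    """One 30-frame cell rendered to a two-channel series (reporter on)."""
    params = SimulationParams(n_frames=30, reporter_onset_frame=-200)
    truth = simulate_cell(params, seed=3)
    series, meta = render_image_series(truth, small_geometry, seed=103)
    return truth, series, meta
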