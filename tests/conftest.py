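import numpy as np
import pytest

from cytogmd.synthetic_data import default_params, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-default synthetic cohort (41 AD / 21 HC, 27 regions)."""
    table, truth = simulate_cohort(default_params(seed=20260924))
    return table, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with every noise source switched off: trajectories are
    exactly linear and replicate scans identical."""
    params = default_params(
        random_intercept_sd=0.0,
        random_slope_sd=0.0,
        within_session_noise_sd=0.0,
        mmse_noise_sd=0.0,
        seed=7,
    )
    table, truth = simulate_cohort(params)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
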