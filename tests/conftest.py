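import numpy as np
import pytest

from traitscan import CohortSpec, first_level_contrasts, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects on a 16^3 grid with the default injected effects."""
    spec = CohortSpec(n_subjects=12, grid_shape=(16, 16, 16), rng_seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """3 subjects, all stochastic BOLD components off except the pattern."""
    spec = CohortSpec(
        n_subjects=3,
        grid_shape=(16, 16, 16),
        noise_sd=0.0,
        gain_noise_sd=0.0,
        seed_fluct_sd=0.0,
        coupling_base_gain=0.0,
        coupling_slopes={"noncarrier": 0.0, "carrier": 0.0},
        rng_seed=5,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_contrasts(small_cohort):
    return first_level_contrasts(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
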