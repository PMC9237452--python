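import numpy as np
import pytest

from cycleconn.synthetic import DynamicSimParams, StaticSimParams, gen_dynamic_cohort, gen_static_cohort


@pytest.fixture(scope="session")
def small_static_cohort():
    """Planted-effect static cohort, small enough for fast end-to-end tests."""
    return gen_static_cohort(
        StaticSimParams(p=60, t=200, n_days=12, seed=11)
    )


@pytest.fixture(scope="session")
def small_dynamic_cohort():
    """Planted two-state dynamic cohort with a large occupancy shift."""
    return gen_dynamic_cohort(
        DynamicSimParams(
            p=24, k_true=2, fo_shift=0.2, t=150, n_days=10, phase_noise_sd=0.2,
            seed=5,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
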