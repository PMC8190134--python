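import numpy as np
import pytest

from gaitfall import synthetic


@pytest.fixture(scope="session")
def zero_noise_walk():
    plan = synthetic.GaitPlan(n_strides=5, stride_time_mean=1.0,
                              stride_time_sd=0.0, noise_sd=0.0, seed=1)
    return plan, synthetic.simulate_imu_walk(plan)


@pytest.fixture(scope="session")
def default_cohort():
    spec = synthetic.default_cohort_spec(seed=42)
    return synthetic.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthetic.default_cohort_spec(n_participants=300, seed=7)
    return synthetic.simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
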