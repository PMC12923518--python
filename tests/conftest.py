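import numpy as np
import pytest

import lossvol as lv


@pytest.fixture(scope="session")
def schedule():
    return lv.generate_schedule("stable_first", seed=101)


@pytest.fixture(scope="session")
def subject(schedule):
    params = dict(omega=-3.0, beta=2.0, rho=1.2)
    ds = lv.simulate_agent("hgf2_loss", params, schedule, seed=202)
    ds.subject_id = "S001"
    return ds


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic subjects with the default covariate-linked parameters."""
    cfg = lv.CohortConfig(n_subjects=20, seed=11)
    return lv.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
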