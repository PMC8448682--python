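import numpy as np
import pytest

import lipdecode as L


@pytest.fixture(scope="session")
def small_session():
    """A small but complete session: 12 neurons, tau=0, reduced trial counts."""
    cohort = L.make_cohort(12, seed=101, tau=0.0)
    cfg = L.SessionConfig(n_neurons=12, n_regular_per_position=6,
                          n_interceptive_per_direction=8, seed=101)
    trials = L.simulate_session(cohort, cfg)
    return cohort, cfg, trials


@pytest.fixture(scope="session")
def small_model(small_session):
    _, _, trials = small_session
    return L.SaccadeDecodingModel(trials)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
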