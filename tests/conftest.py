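import numpy as np
import pytest

from latewave.simulate import CohortConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One small MST session reused across read-only tests."""
    cfg = CohortConfig.MST(n_trials=150, n_neurons=8, seed=11)
    return simulate_session(cfg, session_id="fixture")


@pytest.fixture(scope="session")
def visual_trials(small_session):
    t = small_session.trials
    return t[t["trial_type"] == "visual"].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
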