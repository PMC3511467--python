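import numpy as np
import pytest

from discountfit import AgentSpec, TrialRecord, run_adaptive_session


@pytest.fixture(scope="session")
def toy_trials():
    """Three printed toy trials: LL offers 30/50/70 at 7/30/180 days."""
    return [
        TrialRecord("t1", 20.0, 30.0, 7.0, "LL"),
        TrialRecord("t1", 20.0, 50.0, 30.0, "LL"),
        TrialRecord("t1", 20.0, 70.0, 180.0, "SS"),
    ]


@pytest.fixture(scope="session")
def h_agent_trials():
    """Adaptive-session trials of a moderately noisy hyperbolic agent."""
    agent = AgentSpec("h01", "H", (0.02,), 1.0)
    return run_adaptive_session(agent, seed=7).trials


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
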