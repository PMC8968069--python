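import numpy as np
import pytest

from seegstate.containers import ChannelInfo, EventTable, Recording
from seegstate.synthetic import default_paradigm, default_profiles, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A short but complete session: 20 trials, 20 channels, strong planted
    responses on A2/A5/A8/B3/B7 (shared across tests; treat as read-only)."""
    cfg = default_paradigm(n_trials=20)
    return simulate_session(cfg, seed=1234)


@pytest.fixture(scope="session")
def small_traces(small_session):
    from seegstate.pipeline import preprocess_session

    rec, _, _ = small_session
    return preprocess_session(rec, ["high_gamma", "erp"])


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def three_contact_recording():
    """One shaft, three contacts, simple deterministic signals."""
    data = np.vstack(
        [np.full(100, 1.0), np.full(100, 5.0), np.full(100, 2.0)]
    )
    channels = [ChannelInfo(f"A{i+1}", "A", i + 1) for i in range(3)]
    return Recording(data, 1000.0, channels)
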