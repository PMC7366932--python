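import numpy as np
import pytest

from swdscope.synthetic import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def short_session():
    """One 10-min default synthetic session shared across detector tests."""
    cfg = SessionConfig(duration_s=600.0, seed=11, glitch_rates={})
    eeg, traj, gt = simulate_session(cfg)
    return cfg, eeg, traj, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
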