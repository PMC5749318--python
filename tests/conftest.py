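import numpy as np
import pytest

from preictal.synth import SynthConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def seizure_session():
    """A 22-minute seizure session: interictal 0-10 min, preictal 10-20 min,
    onset at minute 20 (the earliest the eligibility rule allows)."""
    cfg = SynthConfig(
        session_minutes=22.0, onset_minute=20.0, preictal_minutes=10.0, seed=11
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def quiet_session():
    """A short seizure-free session."""
    cfg = SynthConfig(session_minutes=2.0, onset_minute=None, seed=5)
    return generate_session(cfg)
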