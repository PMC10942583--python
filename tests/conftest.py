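import numpy as np
import pytest

from socialphys import SynthConfig, simulate_session
from socialphys.core import SessionTimeline


@pytest.fixture(scope="session")
def short_cfg():
    """Scaled-down session (3 min, few units) for fast unit tests."""
    return SynthConfig(
        baseline_duration=20.0, interaction_duration=160.0,
        n_bouts=8, n_pc=2, n_dn=3, n_acc=6, seed=42,
    )


@pytest.fixture(scope="session")
def session(short_cfg):
    return simulate_session(short_cfg)


@pytest.fixture(scope="session")
def default_session():
    """One full-size session at the generator defaults (8 min, 30 Hz)."""
    return simulate_session(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def timeline():
    return SessionTimeline.regular(60.0, 30.0)
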