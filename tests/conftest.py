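import numpy as np
import pytest

from mcffbayes import PriorBounds, SessionStructure


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def structure6():
    """Full-length six-session layout (no pre-training)."""
    return SessionStructure(n_sessions=6, trials_per_session=320, pretrain_trials=0)


@pytest.fixture
def small_structure():
    """Short two-session layout for fast simulation tests."""
    return SessionStructure(n_sessions=2, trials_per_session=40, pretrain_trials=0)


@pytest.fixture
def bounds2():
    return PriorBounds.default(2)


@pytest.fixture
def bounds6():
    return PriorBounds.default(6)


@pytest.fixture
def bounds14():
    return PriorBounds.default(14)
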