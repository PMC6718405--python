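import warnings

import numpy as np
import pytest

from prestim.design import DesignSpec, GeneratorParams, simulate_session
from prestim.preprocess import average_prestim, detrend_blocks

# scikit-learn 1.8+ warns about the (unused) penalty alias internally
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A 48-trial session spec for fast structural tests."""
    return DesignSpec(repeats=2, n_blocks=4, n_sensors=12)


@pytest.fixture(scope="session")
def default_session():
    """One full default-scale session, shared across read-only tests."""
    return simulate_session(seed=11)


@pytest.fixture(scope="session")
def default_states(default_session):
    """Brain-state matrix of the shared session (detrended, averaged)."""
    return average_prestim(detrend_blocks(default_session.epochs))
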