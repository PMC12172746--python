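import numpy as np
import pytest

from tapflow import synthio
from tapflow.montage import Montage


@pytest.fixture(scope="session")
def small_session():
    """A 2.5-minute 16-channel session with EEG, shared across tests."""
    return synthio.simulate_session(synthio.scaled_config(seed=0))


@pytest.fixture(scope="session")
def movement_session():
    """Movement/force-only session used by alignment and detection tests."""
    return synthio.simulate_session(
        synthio.scaled_config(seed=5, clock_offset_ms=350.0), with_eeg=False)


@pytest.fixture(scope="session")
def montage16():
    return Montage(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
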