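import numpy as np
import pytest

from assrconn.synth import EEGSimConfig, generate_eeg_epochs


@pytest.fixture(scope="session")
def small_epochs():
    """8-channel, strong-snr synthetic recording shared across tests."""
    return generate_eeg_epochs(EEGSimConfig(n_channels=8, snr=4.0, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
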