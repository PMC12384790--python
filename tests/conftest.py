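import numpy as np
import pytest

from eegstc import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A short, well-behaved synthetic recording configuration."""
    return sg.SynthConfig(n_channels=12, K=4, fs=250.0, duration=4.0, snr_db=30, seed=7)


@pytest.fixture
def small_recording(small_config):
    templates = sg.generate_templates(
        small_config.n_channels, small_config.K, seed=small_config.seed
    )
    seq = sg.generate_label_sequence(small_config)
    rec = sg.generate_eeg(templates, seq, small_config)
    return templates, seq, rec
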