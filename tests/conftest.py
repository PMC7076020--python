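import numpy as np
import pytest

from mweeg.synth import SynthConfig, make_participants, null_config


@pytest.fixture(scope="session")
def small_eeg_cfg():
    """Short, low-rate EEG so signal-path tests stay fast.

    10-s segments at 100 Hz give 1000-sample segments; the 2000-ms HFD
    window is 200 samples, comfortably above 2*k_max.
    """
    return SynthConfig(n_ctrl=2, n_szq=2, sfreq=100.0, segment_length=10.0, seed=7)


@pytest.fixture(scope="session")
def study_cfg():
    """Full-size study conditions (45 participants) for record-level stats."""
    return SynthConfig(seed=3)


@pytest.fixture(scope="session")
def null_cfg():
    return null_config()


@pytest.fixture(scope="session")
def participants(study_cfg):
    return make_participants(study_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
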