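import numpy as np
import pytest

from msfusion import eeg as eegmod
from msfusion import simulate as sim
from msfusion.config import SimConfig
from msfusion.io import template_positions


@pytest.fixture(scope="session")
def positions32():
    return template_positions(32)


@pytest.fixture(scope="session")
def protos6(positions32):
    rng = np.random.default_rng(500)
    return sim.gen_prototypes(6, 32, rng, positions=positions32)


@pytest.fixture(scope="session")
def small_cfg():
    """Short two-trial session used by most signal-level tests."""
    return SimConfig(trial_duration_s=60.0, n_trials=2, rest_duration_s=10.0,
                     seed=0)


@pytest.fixture(scope="session")
def small_session(small_cfg, protos6):
    """One synthetic subject: ground truth, EEG and fNIRS."""
    truth = sim.gen_state_sequence(small_cfg, 11, prototypes=protos6)
    eeg = sim.gen_eeg(truth, small_cfg, 12, error_burst_gain=0.5)
    fnirs = sim.gen_fnirs(eeg, truth, small_cfg, 13)
    return small_cfg, truth, eeg, fnirs


@pytest.fixture(scope="session")
def clean_eeg(small_session):
    """Preprocessed EEG of the shared synthetic subject."""
    _, _, eeg, _ = small_session
    clean, report = eegmod.preprocess_eeg(eeg)
    return clean, report
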