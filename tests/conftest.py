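import numpy as np
import pytest

from eegdta import preprocessing as pp
from eegdta import simulate as sim


@pytest.fixture(scope="session")
def quiet_noise():
    """Low-amplitude background with no blink/EMG artifacts."""
    return sim.NoiseParams(pink_noise_sd=1.0, blink_rate=0.0,
                           emg_burst_rate=0.0)


@pytest.fixture(scope="session")
def small_session(quiet_noise):
    """A 8-trial high-SNR session shared across read-only tests."""
    cfg = sim.SessionConfig(n_trials_per_arm=4, seed=7)
    return sim.generate_session(cfg, noise=quiet_noise)


@pytest.fixture(scope="session")
def clean_small(small_session):
    """(preprocessor, cleaned recording) for the shared session."""
    pre = pp.Preprocessor(pp.PreprocConfig(), run_ica=False)
    return pre, pre.fit_transform(small_session)


@pytest.fixture(scope="session")
def epochs_small(clean_small):
    pre, clean = clean_small
    return pre.extract(clean)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
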