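import numpy as np
import pytest

from eegfmri.features import extract_features
from eegfmri.hrf import DEFAULT_DELAYS, HRFParams, delay_family
from eegfmri.synth import GroupConfig, simulate_subject


@pytest.fixture(scope="session")
def fast_config() -> GroupConfig:
    """Compact study conditions for fast end-to-end tests.

    Two RSNs with one region each, three channels, two minutes at 125 Hz:
    small enough that a full subject pipeline runs in about a second while
    every stage still exercises its real code path.
    """
    return GroupConfig(n_subjects=3, duration_s=120.0, tr=2.0, fs=125.0,
                       n_rsn=2, regions_per_rsn=1, n_channels=3,
                       true_delay=6.0, coupling_magnitude=0.5, seed=11)


@pytest.fixture(scope="session")
def fast_subject(fast_config):
    return simulate_subject(fast_config, 101)


@pytest.fixture(scope="session")
def fast_family(fast_config):
    return delay_family(DEFAULT_DELAYS, HRFParams(dt=fast_config.tr))


@pytest.fixture(scope="session")
def fast_features(fast_subject, fast_config, fast_family):
    return extract_features(
        {"scalp": (fast_subject.eeg_scalp, fast_subject.chan_labels),
         "source": (fast_subject.eeg_source, fast_subject.region_labels)},
        fast_config.fs, fast_config.tr, fast_family, fast_config.bands)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
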