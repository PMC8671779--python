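import numpy as np
import pytest

from eegbiotype import SimConfig, GroupParams, simulate_subject


@pytest.fixture(scope="session")
def small_config():
    """Compact study configuration used across EEG-level tests."""
    return SimConfig(
        n_channels=4,
        sampling_rate=250.0,
        n_trials_target=40,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_recording(small_config):
    """One simulated subject with homogeneous, well-calibrated coupling."""
    cfg = SimConfig(
        **{**small_config.__dict__, "coupling_sd": 0.0, "noise_sd": 0.3}
    )
    rec, truth = simulate_subject(cfg, GroupParams("g", 0.5, 0.5), seed=3)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
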