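import numpy as np
import pytest

from graspkin import MirrorModel, TrialConfig, synth_trial


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free trial with ground truth."""
    cfg = TrialConfig(noise_acc_sigma=0.0, noise_angle_sigma=0.0,
                      noise_gyro_sigma=0.0, seed=1)
    return synth_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """One default-noise trial with ground truth."""
    return synth_trial(TrialConfig(seed=42))


@pytest.fixture(scope="session")
def small_mirror():
    """A half-size mirror model for fast vision tests."""
    return MirrorModel(center_px=(240.0, 320.0), r_inner_px=60.0,
                       r_outer_px=200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
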