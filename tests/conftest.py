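import numpy as np
import pytest
from hypothesis import settings

from pulseforge import SynthConfig, synth_clip

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_clip():
    """A 32x32, 60-frame noiseless pulsatile clip at 72 BPM."""
    cfg = SynthConfig(hr_bpm=72.0, d=60, h=32, w=32, noise_sd=0.0,
                      illum_amp=0.0, jitter_px=0, amp_mod_sd=0.0, seed=3)
    return synth_clip(cfg)


@pytest.fixture(scope="session")
def noisy_clip():
    cfg = SynthConfig(hr_bpm=66.0, d=60, h=32, w=32, noise_sd=0.02,
                      jitter_px=1, seed=4)
    return synth_clip(cfg)
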