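import numpy as np
import pytest

from thetalink.io import Recording
from thetalink.synthdata import SynthConfig, generate_lfp_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_pair():
    """A strongly coupled 2 kHz pair reused across spectral tests."""
    cfg = SynthConfig(duration=100.0, fs_raw=2000.0, coupling_c=0.8, seed=42)
    rec_a, rec_b, truth = generate_lfp_pair(cfg)
    return rec_a, rec_b, truth, cfg


@pytest.fixture(scope="session")
def cosine_recording():
    """Pure 4 Hz cosine at the conditioned LFP rate (30 s)."""
    fs = 2000.0
    t = np.arange(0, 30, 1 / fs)
    return Recording(signal=np.cos(2 * np.pi * 4.0 * t), fs=fs)
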