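import numpy as np
import pytest

from lfpkit import ContinuousSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_1khz():
    """60 s of a 2.0-amplitude 6 Hz sinusoid sampled at 1 kHz."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    return ContinuousSignal((2.0 * np.sin(2 * np.pi * 6.0 * t))[None, :], fs)


@pytest.fixture
def white_noise(rng):
    """60 s of unit-variance white noise at 1 kHz."""
    return ContinuousSignal(rng.standard_normal(60000)[None, :], 1000.0)
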