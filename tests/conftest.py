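import numpy as np
import pytest

from speechtrf import synthgen as sg
from speechtrf.containers import EEGRecording, FeatureSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def speech_stimulus():
    """One 6-second speech-like trial at 16384 Hz (shared across tests)."""
    f0 = sg.make_f0_trajectory(6.0, 64.0, seed=101)
    return sg.make_speech_like_stimulus(f0, rate=16384.0, seed=102)


@pytest.fixture(scope="session")
def constant_f0_stimulus():
    """Constant-107-Hz pulse train, 4 seconds at 16384 Hz."""
    f0 = sg.make_f0_trajectory(4.0, 64.0, excursion=0.0)
    return sg.make_speech_like_stimulus(f0, rate=16384.0, seed=103)


def tone(freq, duration, rate, amplitude=1.0):
    t = np.arange(int(round(duration * rate))) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


@pytest.fixture
def make_tone():
    return tone


@pytest.fixture
def white_trial():
    """White feature + known 30-tap kernel + noiseless response."""
    r = np.random.default_rng(7)
    n = 4000
    x = r.standard_normal(n)
    h = r.standard_normal(30)
    y = np.convolve(x, h)[:n]
    feature = FeatureSeries(x, 1000.0, label="white")
    eeg = EEGRecording([y[None, :]], 1000.0, ["Cz"])
    return feature, h, eeg
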