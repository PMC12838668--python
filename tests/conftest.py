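import numpy as np
import pytest

from sleepmod import EEGRecording, Hypnogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """60 s of a clean 10 Hz tone at 100 Hz sampling."""
    fs = 100.0
    t = np.arange(0, 60, 1 / fs)
    return EEGRecording("tone", "C4-M1", fs, np.cos(2 * np.pi * 10 * t))


@pytest.fixture
def noisy_recording(rng):
    """90 s of band-limited noise-like EEG surrogate at 100 Hz."""
    fs = 100.0
    n = int(90 * fs)
    x = rng.standard_normal(n)
    return EEGRecording("noise", "C4-M1", fs, x)


def am_signal(f_c, f_m, depth=0.8, duration_s=60.0, fs=100.0, amp=1.0):
    """Amplitude-modulated tone: amp*(1 + depth*cos(2pi f_m t))*cos(2pi f_c t)."""
    t = np.arange(0, duration_s, 1 / fs)
    return amp * (1 + depth * np.cos(2 * np.pi * f_m * t)) * np.cos(2 * np.pi * f_c * t)


@pytest.fixture
def markov_hypnogram():
    from sleepmod.synthetic_data import generate_hypnogram

    return generate_hypnogram(200, seed=7)
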