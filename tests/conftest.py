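import numpy as np
import pytest

from bleatkit.audio_io import FrameSpec, Waveform

RATE = 22_050


@pytest.fixture(scope="session")
def rate() -> int:
    return RATE


@pytest.fixture(scope="session")
def frame_spec() -> FrameSpec:
    return FrameSpec()


def make_sine(freq: float, duration_s: float = 2.0, rate: int = RATE, amplitude: float = 1.0) -> Waveform:
    t = np.arange(round(duration_s * rate)) / rate
    return Waveform(samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate)


@pytest.fixture(scope="session")
def sine_440() -> Waveform:
    return make_sine(440.0)


@pytest.fixture(scope="session")
def sine_220() -> Waveform:
    return make_sine(220.0, amplitude=0.9)


@pytest.fixture(scope="session")
def silence() -> Waveform:
    return Waveform(samples=np.zeros(2 * RATE), rate=RATE)


@pytest.fixture(scope="session")
def white_noise() -> Waveform:
    rng = np.random.default_rng(1234)
    return Waveform(samples=0.5 * rng.uniform(-1, 1, 2 * RATE), rate=RATE)
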