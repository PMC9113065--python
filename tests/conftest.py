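import numpy as np
import pytest

from halt.audio_levels import AudioSignal
from halt import electroacoustics as ea
from halt import virtual_lab as vl

RATE = 48000


@pytest.fixture(scope="session")
def rate() -> int:
    return RATE


@pytest.fixture(scope="session")
def ess_pair():
    """A wide sweep (10 Hz – 22 kHz, 3 s) and its inverse filter, shared
    by the deconvolution tests."""
    return ea.generate_ess(10.0, 22000.0, 3.0, RATE)


@pytest.fixture(scope="session")
def default_stimuli():
    """The stimulus set shared by all simulated sessions."""
    return vl.build_default_stimuli(seed=0, rate=RATE)


@pytest.fixture(scope="session")
def flat_simulator(default_stimuli):
    return vl.SessionSimulator(vl.flat_device(), stimuli=default_stimuli)


@pytest.fixture(scope="session")
def laptop_simulator(default_stimuli):
    return vl.SessionSimulator(vl.laptop_model(), stimuli=default_stimuli)


def sine(freq: float, duration: float = 1.0, amplitude: float = 1.0,
         rate: int = RATE, phase: float = 0.0) -> AudioSignal:
    t = np.arange(int(round(duration * rate))) / rate
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq * t + phase), rate)
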