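import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sdpn import VOWEL_PRESETS, Waveform, synth_vowel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

RATE = 22050.0


@pytest.fixture(scope="session")
def rate() -> float:
    return RATE


@pytest.fixture(scope="session")
def vowel_i() -> Waveform:
    """The standard /i/ fixture: 0.5 s, peak-normalized, 22.05 kHz."""
    return synth_vowel(VOWEL_PRESETS["i"], RATE)


@pytest.fixture()
def tone():
    """Factory for steady test tones."""

    def _tone(freq: float, amplitude: float = 1.0, duration: float = 0.5,
              rate: float = RATE) -> Waveform:
        t = np.arange(int(round(duration * rate))) / rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)

    return _tone
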