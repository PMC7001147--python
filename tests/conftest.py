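import numpy as np
import pytest

from envtacs import Envelope, gen_speech_like_envelope


@pytest.fixture(scope="session")
def speech_env() -> Envelope:
    """A 30 s speech-like envelope shared by read-only tests."""
    return gen_speech_like_envelope(30.0, rate=100.0, seed=0)


@pytest.fixture()
def grid_cosine_env() -> Envelope:
    """A pure cosine exactly on the FFT grid (2 Hz, 10 s at 100 Hz)."""
    rate, f, n = 100.0, 2.0, 1000
    t = np.arange(n) / rate
    return Envelope(samples=np.cos(2 * np.pi * f * t), rate=rate)
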