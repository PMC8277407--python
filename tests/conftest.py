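import numpy as np
import pytest

from wheezekit.audio_io import DualChannelRecording
from wheezekit.config import CANONICAL_FS


@pytest.fixture
def fs() -> int:
    return CANONICAL_FS


def make_recording(lung, env=None, fs=CANONICAL_FS):
    return DualChannelRecording(lung=np.asarray(lung, float), env=env, fs=fs)


@pytest.fixture
def sine():
    def _sine(freq_hz, duration_s, fs=CANONICAL_FS, amp=1.0, phase=0.0):
        t = np.arange(int(round(duration_s * fs))) / fs
        return amp * np.sin(2 * np.pi * freq_hz * t + phase)

    return _sine
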