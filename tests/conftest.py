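import numpy as np
import pytest

FS = 2048.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def t_2s():
    return np.arange(int(2 * FS)) / FS


def tone(freq, t, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def make_tone(t_2s):
    return lambda freq, amp=1.0, phase=0.0: tone(freq, t_2s, amp, phase)
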