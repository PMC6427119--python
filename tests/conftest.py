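import numpy as np
import pytest

from motionkit.skeleton import AngleSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_signal(values, rate: float = 100.0, name: str = "sig") -> AngleSignal:
    """Uniform-grid AngleSignal from raw values (test helper)."""
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) / rate
    return AngleSignal(name=name, t=t, values=values, rate=rate)


def raised_cosine_train(durations, amplitudes, base=0.0, rate=100.0, lead=0.0):
    """Contiguous min-max-min raised-cosine cycles on a uniform grid."""
    durations = np.asarray(durations, float)
    amplitudes = np.asarray(amplitudes, float)
    starts = lead + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    total = lead + durations.sum() + lead
    t = np.arange(int(round(total * rate)) + 1) / rate
    v = np.full(t.shape, float(base))
    for s, d, a in zip(starts, durations, amplitudes):
        m = (t >= s) & (t <= s + d)
        v[m] = base + a * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - s) / d))
    return AngleSignal("train", t, v, rate)
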