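import math

import numpy as np
import pytest
from hypothesis import settings

import dressedepr as de

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ops2():
    return de.two_spin_ops()


@pytest.fixture()
def perp_pair():
    """Reference pair: 4.1 nm ruler, perpendicular orientation, 100 MHz lock."""
    return de.SpinPairParams(r=4.1, theta=math.pi / 2, omega1_nu=100.0)


@pytest.fixture()
def weak_pair():
    """Pair with negligible coupling (magic angle, long distance)."""
    return de.SpinPairParams(r=8.0, theta=de.MAGIC_ANGLE, omega1_nu=100.0)


def dominant_frequency(time_us: np.ndarray, amp: np.ndarray,
                       pad: int = 32) -> float:
    """Zero-padded, windowed FFT peak with parabolic refinement (MHz)."""
    y = np.asarray(amp, dtype=float)
    y = y - y.mean()
    n = y.size
    spec = np.abs(np.fft.rfft(y * np.hamming(n), pad * n))
    freq = np.fft.rfftfreq(pad * n, d=float(time_us[1] - time_us[0]))
    i = int(np.argmax(spec))
    if 0 < i < spec.size - 1:
        y0, y1, y2 = spec[i - 1], spec[i], spec[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            i = i + 0.5 * (y0 - y2) / denom
    return float(np.interp(i, np.arange(freq.size), freq))
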