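import numpy as np
import pytest

from netstab import BoldSeries, MotionTable


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_series(rng):
    """Seeded 6x6x4 random BOLD series, 60 frames at TR 3 s."""
    return BoldSeries(rng.normal(size=(6, 6, 4, 60)), tr_seconds=3.0)


@pytest.fixture
def still_motion():
    """Near-zero smooth motion, 60 frames."""
    rng = np.random.default_rng(7)
    trans = np.cumsum(rng.normal(0, 1e-3, (60, 3)), axis=0)
    rots = np.cumsum(rng.normal(0, 1e-5, (60, 3)), axis=0)
    return MotionTable(trans, rots)


def tone(freq_hz, n, tr, amplitude=1.0, phase=0.0):
    """Pure sinusoid sampled at TR; helper shared across spectral tests."""
    t = np.arange(n) * tr
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


def on_bin_freq(target_hz, n, tr):
    """Closest DFT-grid frequency to target for an n-sample TR-spaced series."""
    k = round(target_hz * n * tr)
    return k / (n * tr)
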