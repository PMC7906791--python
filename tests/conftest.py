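import numpy as np
import pytest

from slowosc.timeseries import BandSpec, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def human_band():
    return BandSpec(0.01, 0.1)


@pytest.fixture
def sine_ts():
    """0.05 Hz unit sine, 900 s at 1 s sampling."""
    t = np.arange(900.0)
    return TimeSeries(np.sin(2 * np.pi * 0.05 * t), dt=1.0, label="sine05")


@pytest.fixture
def noisy_ts(rng):
    """Band-limited-ish noisy trace for generic preprocessing tests."""
    from slowosc.synth import band_limited_noise

    x = band_limited_noise(900, 1.0, BandSpec(0.01, 0.1), rng)
    x = x + 0.5 * rng.standard_normal(900)
    return TimeSeries(x, dt=1.0, label="noisy")
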