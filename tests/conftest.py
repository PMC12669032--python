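import numpy as np
import pytest

from xenoscreen.growth import GrowthCurve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_curve():
    """Factory for growth curves with sensible defaults."""

    def _make(od, times=None, plate="P1", well="A01", strain="s1", rep=1):
        od = np.asarray(od, dtype=float)
        if times is None:
            times = np.arange(od.size, dtype=float)
        return GrowthCurve(plate, well, strain, rep, np.asarray(times, float), od)

    return _make
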