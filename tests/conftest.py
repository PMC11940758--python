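import numpy as np
import pytest

from actipat.preprocess import EpochSeries
from actipat.synthetic import ActivityModelParams


@pytest.fixture
def make_series():
    """Factory for EpochSeries on a 30-s grid starting Monday midnight."""

    def _make(values, wear=None, start="2015-03-02", epoch_seconds=30):
        values = np.asarray(values, dtype=float)
        return EpochSeries(start, epoch_seconds, values, wear)

    return _make


@pytest.fixture
def params():
    return ActivityModelParams()


@pytest.fixture
def params_no_nonwear():
    return ActivityModelParams(nonwear_episodes_per_day=0.0)
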