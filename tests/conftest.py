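import numpy as np
import pytest

from emovis.synthetic import make_observer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def typical_observer():
    return make_observer("typical")


@pytest.fixture
def clean_observer():
    """Typical observer without blinks/anticipations/lapses: pure latency +
    duration + processing-time machinery, for recovery tests."""
    return make_observer("typical", blink_rate=0.0, anticipatory_rate=0.0, lapse_rate=0.0)
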