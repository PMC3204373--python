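import numpy as np
import pytest

from dynsynrl import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def poisson_events(rng):
    """A fixed 50-Hz-like random spike pattern on a 200-ms grid."""
    return SpikeTrain.from_binary(rng.random(200) < 0.05)


def make_train(events, length_ms=200):
    return SpikeTrain(length_ms=length_ms, events=np.asarray(events, dtype=np.int64))
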