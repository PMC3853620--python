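import numpy as np
import pytest

from scrglm.core_io import Condition, EventModel


@pytest.fixture
def rng():
    return np.random.default_rng(20231209)


@pytest.fixture
def jittered_events(rng):
    """Two interleaved conditions with irregular onsets (full-rank designs)."""
    on_a = np.cumsum(rng.choice([7.65, 9.0, 10.35], 12)) + 2.0
    on_b = on_a + rng.choice([4.2, 4.6, 5.1], 12)
    return EventModel((Condition("a", on_a), Condition("b", on_b)))


@pytest.fixture
def recording_length(jittered_events):
    """Samples at 10 Hz covering the events plus 40 s tail."""
    return int((jittered_events.condition("b").onsets[-1] + 40.0) * 10)
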