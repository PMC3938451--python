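import numpy as np
import pytest

from sra.beats import beat_series_from_intervals
from sra.classifier import default_model


@pytest.fixture(scope="session")
def model():
    """The shipped fixture risk model (trained once, versioned)."""
    return default_model()


@pytest.fixture
def regular_beats():
    """60 s of perfectly regular 75 bpm rhythm (75 beats)."""
    return beat_series_from_intervals(np.full(74, 800.0))


def constant_series(value=800.0, n=100):
    return beat_series_from_intervals(np.full(n, float(value)))


@pytest.fixture
def make_constant_beats():
    return constant_series
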