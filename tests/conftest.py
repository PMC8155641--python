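import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from spikeconn import Movie, RawTrace


@pytest.fixture
def small_movie():
    """20-frame 8x8 movie with a known gradient pattern."""
    rng = np.random.default_rng(7)
    frames = rng.integers(0, 1000, size=(20, 8, 8)).astype(np.uint16)
    return Movie(frames=frames, frame_rate=500.0)


@pytest.fixture
def flat_trace():
    """Constant-plus-noise trace long enough for clustering preconditions."""
    rng = np.random.default_rng(11)
    return RawTrace(values=100.0 + rng.normal(0, 0.5, size=2000), frame_rate=500.0)
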