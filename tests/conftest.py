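import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from madrnet import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """The small configuration used for capacity and shape checks."""
    return ModelConfig(in_channels=1, num_classes=1, input_size=64,
                       channel_progression=(4, 8, 16, 32, 64, 128))


@pytest.fixture
def micro_cfg():
    """A depth-1 configuration small enough for fast end-to-end runs."""
    return ModelConfig(in_channels=1, num_classes=1, input_size=32,
                       channel_progression=(2, 4))
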