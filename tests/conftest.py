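import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from synaptoscope import three_stage_protocol, control_only_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def long_protocol():
    """10-min control / drug / wash with full washout persistence."""
    return three_stage_protocol(600.0, 600.0, 600.0)


@pytest.fixture
def short_protocol():
    return three_stage_protocol(120.0, 120.0, 120.0)


@pytest.fixture
def baseline_protocol():
    return control_only_protocol(600.0)
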