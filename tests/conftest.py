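import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smlmtopo import FieldSpec, ClusterPatternSpec, simulate_clustered


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def small_field():
    return FieldSpec(2000.0, 2000.0)


@pytest.fixture
def clustered_table():
    """Ten well-separated disc clusters of 100 points, R = 50 nm."""
    spec = ClusterPatternSpec(10, 100, 50.0)
    return simulate_clustered(spec, FieldSpec(24_000.0, 24_000.0), seed=42)
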