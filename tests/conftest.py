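import numpy as np
import pytest

from carsae.geography import RegionGraph, adjacency_from_edges
from carsae.synthetic_data import grid_graph


@pytest.fixture
def path4() -> RegionGraph:
    """4-region path graph a-b-c-d."""
    return adjacency_from_edges("abcd", [("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def grid5() -> RegionGraph:
    """5x5 Queen lattice (25 regions)."""
    return grid_graph(5, 5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
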