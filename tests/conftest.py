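import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return nx.cycle_graph(["A", "B", "C"])


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def star5():
    return nx.star_graph(["HUB", "L1", "L2", "L3", "L4", "L5"])


@pytest.fixture
def k5():
    return nx.complete_graph(["A", "B", "C", "D", "E"])
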