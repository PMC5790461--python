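import networkx as nx
import pytest

from dsgn.screen import CorrelationRecord


@pytest.fixture
def path_graph():
    """a - b - c."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def triangle_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


def record(drug, gene, pcc=0.8, p=1e-4, n=60):
    return CorrelationRecord(drug, gene, pcc, p, n)


@pytest.fixture
def rec():
    return record
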