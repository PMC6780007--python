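import networkx as nx
import pytest

from netpharm.synthetic import default_bundle


def graph_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return g


@pytest.fixture(scope="session")
def triangle():
    return graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def path3():
    return graph_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def star4():
    return graph_from_edges([("C", f"L{i}") for i in range(1, 5)])


@pytest.fixture(scope="session")
def k4():
    return nx.relabel_nodes(nx.complete_graph(4), str)


@pytest.fixture(scope="session")
def cycle4():
    return nx.relabel_nodes(nx.cycle_graph(4), str)


@pytest.fixture(scope="session")
def bundle():
    """One default study fixture shared across the session."""
    return default_bundle(seed=7)
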