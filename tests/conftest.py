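import itertools

import networkx as nx
import numpy as np
import pytest

from hubtrace.netio import Network


def net_from(edges, nodes=(), name="test"):
    return Network.from_edges(edges, nodes=nodes, name=name)


@pytest.fixture
def k4():
    return net_from(itertools.combinations("ABCD", 2), name="K4")


@pytest.fixture
def star5():
    """Star with centre C and 4 leaves (5 nodes)."""
    return net_from([("C", leaf) for leaf in "WXYZ"], name="S5")


@pytest.fixture
def path3():
    return net_from([("A", "B"), ("B", "C")], name="P3")


@pytest.fixture
def path4():
    return net_from([("A", "B"), ("B", "C"), ("C", "D")], name="P4")


@pytest.fixture
def paw():
    """Triangle A-B-C with a pendant D on A."""
    return net_from([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D")])


@pytest.fixture
def triangle():
    return net_from([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_triangles():
    return net_from([("A", "B"), ("B", "C"), ("A", "C"),
                     ("X", "Y"), ("Y", "Z"), ("X", "Z")])


def random_net(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return net_from(((f"n{u}", f"n{v}") for u, v in g.edges),
                    nodes=(f"n{i}" for i in range(n)),
                    name=f"er{n}_{seed}")


def adj_of(net):
    return {n: set(net.graph.neighbors(n)) for n in net.graph.nodes}
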