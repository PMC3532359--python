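import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from threeprop import WeightedGraph


def graph_from_networkx(g: nx.Graph) -> WeightedGraph:
    nodes = sorted(str(v) for v in g.nodes)
    relabeled = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
    A = nx.to_scipy_sparse_array(relabeled, nodelist=nodes, weight="weight",
                                 dtype=float)
    return WeightedGraph(nodes, sp.csr_array(A))


def random_connected_graph(n: int, p: float, seed: int,
                           weighted: bool = False) -> WeightedGraph:
    """Erdős–Rényi graph conditioned on connectivity (regenerates on failure)."""
    for attempt in range(50):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if nx.is_connected(g):
            break
    else:
        raise RuntimeError("could not draw a connected graph")
    if weighted:
        rng = np.random.default_rng(seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
    mapping = {v: f"v{v:03d}" for v in g.nodes}
    return graph_from_networkx(nx.relabel_nodes(g, mapping))


@pytest.fixture
def k3() -> WeightedGraph:
    """Unweighted triangle a-b-c."""
    A = sp.csr_array(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
    return WeightedGraph(["a", "b", "c"], A)


@pytest.fixture
def path3() -> WeightedGraph:
    """Unweighted path a-b-c."""
    A = sp.csr_array(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float))
    return WeightedGraph(["a", "b", "c"], A)


@pytest.fixture
def star_weighted() -> WeightedGraph:
    """Center `c` joined to three leaves by weight-2 edges."""
    g = nx.Graph()
    for leaf in ("l1", "l2", "l3"):
        g.add_edge("c", leaf, weight=2.0)
    return graph_from_networkx(g)
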