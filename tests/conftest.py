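import numpy as np
import pandas as pd
import pytest

from mdgcn.pair_graph import MDPNodeTable, PairGraph
from mdgcn.similarity import GeneInteractionNetwork


def make_node_table(features: np.ndarray, labels=None, roles=None) -> MDPNodeTable:
    """Node table over arbitrary features, one synthetic pair per node."""
    n = len(features)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)
    roles = ["train"] * n if roles is None else list(roles)
    table = pd.DataFrame({
        "node_id": np.arange(n),
        "mirna": [f"m{i}" for i in range(n)],
        "disease": [f"d{i}" for i in range(n)],
        "label": labels,
        "role": roles,
    })
    return MDPNodeTable(table=table, features=np.asarray(features, dtype=float))


def make_graph(n: int, edges) -> PairGraph:
    e = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    e = np.sort(e, axis=1)
    return PairGraph(n_nodes=n, edges=e, weights=np.ones(len(e)))


@pytest.fixture
def node_factory():
    return make_node_table


@pytest.fixture
def graph_factory():
    return make_graph


@pytest.fixture
def path3(graph_factory):
    """Path a-b-c with degrees 1, 2, 1."""
    return graph_factory(3, [[0, 1], [1, 2]])


@pytest.fixture
def star4(graph_factory):
    """Star: hub 0 with three leaves."""
    return graph_factory(4, [[0, 1], [0, 2], [0, 3]])


@pytest.fixture
def triangle(graph_factory):
    return graph_factory(3, [[0, 1], [1, 2], [0, 2]])


@pytest.fixture
def toy_gene_network():
    return GeneInteractionNetwork(
        genes=["g1", "g2", "g3", "g4"],
        weights={("g1", "g2"): 0.7, ("g2", "g3"): 0.4, ("g3", "g4"): 0.9},
    )
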