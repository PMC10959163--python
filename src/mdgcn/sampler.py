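"""Degree-weighted random edge sampler for minibatch GCN training.

Minibatches are induced subgraphs built from ``M`` edges drawn with
replacement, each edge ``(u, v)`` with probability proportional to
``1/deg(u) + 1/deg(v)``.  On a regular graph this reduces to uniform edge
sampling.  Because induced-subgraph training biases both the loss (nodes
appear with unequal probability) and the aggregation (edges likewise), two
empirical normalization coefficients are pre-estimated from ``N`` trial
samples:

* ``lambda_v = C_v / N`` — the appearance frequency of node ``v``; the
  training loss of each sampled node is divided by it.
* ``alpha_{u,v} = C_{u,v} / C_v`` — edge over node appearance frequency; the
  in-subgraph aggregation term along ``(u, v)`` is divided by it.

``C_{u,v}`` counts induced edges (both endpoints present), which is what the
propagation step actually sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pair_graph import PairGraph
from .similarity import InputError

__all__ = [
    "EdgeProbabilityTable",
    "SubgraphSample",
    "NormalizationCoefficients",
    "edge_probabilities",
    "sample_subgraph",
    "estimate_normalization",
]


@dataclass
class EdgeProbabilityTable:
    """Edge list aligned with its sampling probability vector (sums to 1)."""

    edges: np.ndarray  # (m, 2), u < v, aligned with the graph's edge order
    p: np.ndarray      # (m,) nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.edges) != len(self.p):
            raise InputError("edge list and probability vector disagree")
        if (self.p < 0).any():
            raise InputError("negative edge probability")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise InputError("edge probabilities must sum to 1")


@dataclass
class SubgraphSample:
    """One minibatch: M edge draws and the induced subgraph they span."""

    drawn_edges: np.ndarray    # (M,) indices into the full edge list
    nodes: np.ndarray          # sorted unique endpoint ids
    induced_edges: np.ndarray  # (m_i, 2) full-graph edges with both ends sampled


@dataclass
class NormalizationCoefficients:
    """Empirical bias corrections estimated from N trial subgraphs.

    ``alpha`` is a sparse symmetric matrix with ``alpha[u, v] =
    C_{u,v} / C_v`` (rows normalised by the row node's count; defined only
    where ``C_v > 0``); ``lam[v] = C_v / N``.  Nodes never sampled have
    ``lam = 0`` and are excluded from minibatch losses.
    """

    lam: np.ndarray            # (n,) node appearance frequency C_v / N
    alpha: sp.csr_matrix       # (n, n) C_{u,v} / C_v, row-normalised
    node_counts: np.ndarray    # C_v
    edge_counts: sp.csr_matrix # symmetric C_{u,v}
    n_subgraphs: int


def edge_probabilities(graph: PairGraph) -> EdgeProbabilityTable:
    """Sampling probability of each edge: p(u,v) ∝ 1/deg(u) + 1/deg(v)."""
    if graph.n_edges == 0:
        raise InputError("graph has no edges")
    deg = graph.degrees.astype(float)
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    raw = 1.0 / deg[u] + 1.0 / deg[v]
    return EdgeProbabilityTable(edges=graph.edges, p=raw / raw.sum())


def sample_subgraph(
    graph: PairGraph, probs: EdgeProbabilityTable, m: int, seed: int
) -> SubgraphSample:
    """Draw M edges with replacement and return the induced subgraph."""
    if m < 1:
        raise InputError("M must be >= 1")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(probs.p), size=m, replace=True, p=probs.p)
    nodes = np.unique(probs.edges[drawn])
    in_nodes = np.zeros(graph.n_nodes, dtype=bool)
    in_nodes[nodes] = True
    keep = in_nodes[graph.edges[:, 0]] & in_nodes[graph.edges[:, 1]]
    return SubgraphSample(
        drawn_edges=drawn, nodes=nodes, induced_edges=graph.edges[keep]
    )


def estimate_normalization(
    graph: PairGraph,
    probs: EdgeProbabilityTable,
    m: int,
    n_subgraphs: int,
    seed: int,
) -> NormalizationCoefficients:
    """Estimate alpha/lambda from N independent trial subgraphs."""
    if n_subgraphs < 1:
        raise InputError("N must be >= 1")
    n = graph.n_nodes
    c_v = np.zeros(n, dtype=np.int64)
    eu, ev = [], []
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subgraphs)
    for s in child_seeds:
        sub = sample_subgraph(graph, probs, m, int(s))
        c_v[sub.nodes] += 1
        if len(sub.induced_edges):
            eu.append(sub.induced_edges[:, 0])
            ev.append(sub.induced_edges[:, 1])
    if eu:
        au = np.concatenate(eu)
        av = np.concatenate(ev)
        edge_counts = sp.coo_matrix(
            (np.ones(2 * len(au)),
             (np.concatenate([au, av]), np.concatenate([av, au]))),
            shape=(n, n),
        ).tocsr()
    else:
        edge_counts = sp.csr_matrix((n, n))
    inv_c = np.zeros(n)
    pos = c_v > 0
    inv_c[pos] = 1.0 / c_v[pos]
    alpha = sp.diags(inv_c) @ edge_counts
    return NormalizationCoefficients(
        lam=c_v / n_subgraphs,
        alpha=alpha.tocsr(),
        node_counts=c_v,
        edge_counts=edge_counts,
        n_subgraphs=n_subgraphs,
    )
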