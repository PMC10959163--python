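"""Graph construction over miRNA-disease pair (MDP) nodes.

Link prediction is recast as node classification: every candidate
(miRNA, disease) pair becomes one node whose feature vector concatenates the
miRNA's integrated-similarity row and the disease's integrated-similarity
row.  Three graph architectures are provided:

* :func:`knn_regular_graph` — mutual k-nearest-neighbour graph followed by a
  deterministic repair pass that brings every node to degree exactly ``k``
  (the regular homogeneous architecture).
* :func:`kmeans_graph` — k-means partition of the node features, each cluster
  wired as a clique (the non-regular homogeneous contrast).
* :func:`hetero_graph` — heterogeneous entity graph: two fully connected
  similarity blocks plus the bipartite association block.

Test pairs participate in graph construction as label-masked nodes
(``role="test-masked"``, label 0 in the construction view) so the setting is
transductive without leaking test labels.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .similarity import AssociationMatrix, InputError, SimilarityMatrix

__all__ = [
    "MDPNodeTable",
    "PairGraph",
    "sample_negatives",
    "build_mdp_nodes",
    "knn_regular_graph",
    "kmeans_graph",
    "hetero_graph",
]

_CHUNK = 2048  # rows per block in chunked distance computations


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MDPNodeTable:
    """One row per miRNA-disease pair node.

    ``table`` columns: node_id, mirna, disease, label (0/1), role
    ("train" or "test-masked").  ``features`` is the aligned (n, d) feature
    matrix.  Test-masked nodes keep their true label in ``table`` for
    evaluation; graph construction and training must treat them as label 0
    (see :meth:`construction_labels`).
    """

    table: pd.DataFrame
    features: np.ndarray

    def __post_init__(self) -> None:
        if len(self.table) != len(self.features):
            raise InputError("node table and feature matrix disagree in length")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def roles(self) -> np.ndarray:
        return self.table["role"].to_numpy()

    def construction_labels(self) -> np.ndarray:
        """Labels as visible during graph building/training: test pairs are 0."""
        lab = self.labels.copy()
        lab[self.roles == "test-masked"] = 0
        return lab

    def train_mask(self) -> np.ndarray:
        return self.roles == "train"


@dataclass
class PairGraph:
    """Undirected graph over MDP nodes (or heterogeneous entity nodes).

    Edges are stored once with ``u < v`` and no self-loops; self-connections
    are added at model time via the renormalised adjacency.
    """

    n_nodes: int
    edges: np.ndarray          # (m, 2) int array, u < v
    weights: np.ndarray        # (m,) float
    method: str = "unspecified"
    params: dict = field(default_factory=dict)
    node_features: np.ndarray | None = None
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise InputError("edge list and weight vector disagree in length")
        if len(self.edges):
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise InputError("edges must satisfy u < v (no self-loops)")
            if self.edges.max() >= self.n_nodes or self.edges.min() < 0:
                raise InputError("edge endpoint out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric sparse adjacency (binary by default)."""
        if not len(self.edges):
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        data = self.weights if weighted else np.ones(len(self.edges))
        u, v = self.edges[:, 0], self.edges[:, 1]
        a = sp.coo_matrix(
            (np.concatenate([data, data]),
             (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()


# ---------------------------------------------------------------------------
# negative sampling and node assembly
# ---------------------------------------------------------------------------


def sample_negatives(
    assoc: AssociationMatrix, ratio: float = 1.0, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniformly sample unknown (zero) pairs as negatives, without replacement.

    ``round(ratio * n_positive)`` pairs are drawn; deterministic given seed.
    """
    if ratio <= 0:
        raise InputError("ratio must be positive")
    n_pos = assoc.n_positive
    count = int(round(ratio * n_pos))
    zi, zj = np.nonzero(assoc.values == 0)
    if len(zi) < count:
        raise InputError(
            f"cannot sample {count} negatives from {len(zi)} unknown pairs"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zi), size=count, replace=False)
    pick.sort()
    return [(assoc.mirnas[zi[p]], assoc.diseases[zj[p]]) for p in pick]


def build_mdp_nodes(
    pairs: Iterable[tuple],
    imsm: SimilarityMatrix,
    idsm: SimilarityMatrix,
) -> MDPNodeTable:
    """Assemble the MDP node table from labeled pairs.

    Each pair is ``(mirna, disease, label)`` or ``(mirna, disease, label,
    role)``; the feature vector is the miRNA's IMSM row concatenated with the
    disease's IDSM row.  Pair order is preserved; duplicates are rejected.
    """
    rows, feats = [], []
    seen: set[tuple[str, str]] = set()
    for k, p in enumerate(pairs):
        if len(p) == 3:
            m, d, lab = p
            role = "train"
        elif len(p) == 4:
            m, d, lab, role = p
        else:
            raise InputError(f"pair {p!r} must have 3 or 4 fields")
        m, d = str(m), str(d)
        if (m, d) in seen:
            raise InputError(f"duplicate pair ({m}, {d})")
        seen.add((m, d))
        if lab not in (0, 1):
            raise InputError(f"label {lab!r} for ({m}, {d}) must be 0 or 1")
        if role not in ("train", "test-masked"):
            raise InputError(f"role {role!r} must be 'train' or 'test-masked'")
        feats.append(np.concatenate([imsm.row(m), idsm.row(d)]))
        rows.append((k, m, d, int(lab), role))
    if not rows:
        raise InputError("no pairs supplied")
    table = pd.DataFrame(
        rows, columns=["node_id", "mirna", "disease", "label", "role"]
    )
    return MDPNodeTable(table=table, features=np.asarray(feats, dtype=float))


# ---------------------------------------------------------------------------
# k-NN regular graph
# ---------------------------------------------------------------------------


def _prepare_features(x: np.ndarray, metric: str) -> np.ndarray:
    """Map features so that squared euclidean distance realises the metric."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if metric == "euclidean":
        return x
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return x / norms  # ||a-b||^2 = 2(1 - cos) on the unit sphere
    raise InputError(f"metric must be 'euclidean' or 'cosine', got {metric!r}")


def _sq_dists(x: np.ndarray, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
    """Squared euclidean distances from x[rows] to x[cols] (cols=None: all)."""
    a = x[rows]
    b = x if cols is None else x[cols]
    d2 = (a**2).sum(1)[:, None] + (b**2).sum(1)[None, :] - 2.0 * (a @ b.T)
    np.clip(d2, 0.0, None, out=d2)
    return d2


def _directed_knn(x: np.ndarray, k: int) -> np.ndarray:
    """Per-node k nearest neighbour indices, ties broken by lowest index."""
    n = len(x)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, _CHUNK):
        rows = np.arange(start, min(start + _CHUNK, n))
        d2 = _sq_dists(x, rows)
        d2[np.arange(len(rows)), rows] = np.inf  # exclude self
        # stable sort over index-ordered columns => ties go to lowest index
        out[rows] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def knn_regular_graph(
    nodes: MDPNodeTable, k: int = 5, metric: str = "euclidean"
) -> PairGraph:
    """Build an exactly k-regular graph over the MDP nodes.

    Steps: (i) pairwise distances on the node features; (ii) per-node k
    nearest neighbours, ties broken by lowest node index; (iii) keep mutual
    selections, weighting each kept edge by the mean of the two directed
    distances; (iv) deterministic regularity repair — deficient nodes are
    paired with their nearest deficient non-neighbours (ascending degree
    order) and residual deadlocks are resolved by a single edge relocation —
    until every degree equals ``k``.
    """
    n = len(nodes)
    if k < 1:
        raise InputError("k must be >= 1")
    if k >= n:
        raise InputError(f"k={k} must be smaller than the number of nodes ({n})")
    if (n * k) % 2 != 0:
        raise InputError(f"no {k}-regular graph on {n} nodes exists (n*k is odd)")
    x = _prepare_features(nodes.features, metric)

    nn = _directed_knn(x, k)
    rows = np.repeat(np.arange(n), k)
    directed = sp.csr_matrix(
        (np.ones(n * k, dtype=bool), (rows, nn.ravel())), shape=(n, n)
    )
    mutual = directed.multiply(directed.T).tocoo()
    mask = mutual.row < mutual.col
    eu, ev = mutual.row[mask], mutual.col[mask]

    neigh: list[set[int]] = [set() for _ in range(n)]
    wmap: dict[tuple[int, int], float] = {}
    for u, v in zip(eu.tolist(), ev.tolist()):
        neigh[u].add(v)
        neigh[v].add(u)
    if len(eu):
        dists = np.sqrt(
            np.clip(((x[eu] - x[ev]) ** 2).sum(1), 0.0, None)
        )
        for u, v, w in zip(eu.tolist(), ev.tolist(), dists.tolist()):
            wmap[(u, v)] = w

    deg = np.array([len(s) for s in neigh], dtype=np.int64)
    assert deg.max(initial=0) <= k  # mutual selection cannot exceed k

    def _dist(u: int, v: int) -> float:
        return float(np.sqrt(max(((x[u] - x[v]) ** 2).sum(), 0.0)))

    def _add(u: int, v: int) -> None:
        neigh[u].add(v)
        neigh[v].add(u)
        deg[u] += 1
        deg[v] += 1
        wmap[_edge_key(u, v)] = _dist(u, v)

    def _remove(u: int, v: int) -> None:
        neigh[u].discard(v)
        neigh[v].discard(u)
        deg[u] -= 1
        deg[v] -= 1
        wmap.pop(_edge_key(u, v), None)

    guard = 0
    max_iter = 20 * n * k + 1000
    while True:
        deficient = np.where(deg < k)[0]
        if not len(deficient):
            break
        progress = False
        # pair deficient nodes with their nearest deficient non-neighbours
        dsub = None
        if len(deficient) > 1:
            dsub = _sq_dists(x, deficient, deficient)
            np.fill_diagonal(dsub, np.inf)
        pos = {int(v): i for i, v in enumerate(deficient)}
        order = sorted(deficient.tolist(), key=lambda u: (deg[u], u))
        for u in order:
            while deg[u] < k and dsub is not None:
                cand = [
                    (dsub[pos[u], pos[v]], v)
                    for v in deficient.tolist()
                    if v != u and deg[v] < k and v not in neigh[u]
                ]
                if not cand:
                    break
                _, v = min(cand)
                _add(u, int(v))
                progress = True
                guard += 1
        if progress:
            continue
        # deadlock: the remaining deficient nodes are pairwise adjacent (or a
        # single node is left).  Rotate one edge: pick deficient u (and v,
        # possibly u itself when it is the only one), find an existing edge
        # (a, b) away from them with a not adjacent to u and b not adjacent
        # to v, replace it by (u, a) and (v, b).  Total deficiency drops by
        # 2 every rotation, so this always terminates.
        remaining = sorted(deficient.tolist(), key=lambda t: (deg[t], t))
        u = int(remaining[0])
        v = int(remaining[1]) if len(remaining) > 1 else u
        rotated = False
        for a, b in sorted(wmap):
            for p, q in ((a, b), (b, a)):
                if p in (u, v) or q in (u, v):
                    continue
                if p in neigh[u] or q in neigh[v]:
                    continue
                if u == v and p == q:
                    continue
                _remove(a, b)
                _add(u, p)
                _add(v, q)
                rotated = True
                break
            if rotated:
                break
        if not rotated:
            raise RuntimeError("regularity repair failed: no rotatable edge")
        guard += 1
        if guard > max_iter:
            raise RuntimeError("regularity repair did not converge")

    edges = sorted(wmap)
    e = np.array(edges, dtype=np.int64).reshape(-1, 2)
    w = np.array([wmap[t] for t in edges])
    g = PairGraph(
        n_nodes=n, edges=e, weights=w, method="knn-regular",
        params={"k": k, "metric": metric},
    )
    assert (g.degrees == k).all()
    return g


# ---------------------------------------------------------------------------
# contrast builders
# ---------------------------------------------------------------------------


def kmeans_graph(
    nodes: MDPNodeTable, n_clusters: int = 300, seed: int = 0
) -> PairGraph:
    """Non-regular homogeneous graph: k-means clusters wired as cliques."""
    n = len(nodes)
    if n_clusters < 1 or n_clusters > n:
        raise InputError(f"n_clusters={n_clusters} must be in [1, {n}]")
    if n_clusters == n:
        labels = np.arange(n)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(np.asarray(nodes.features, dtype=np.float64))
    edges = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if len(members) > 1:
            iu, ju = np.triu_indices(len(members), k=1)
            edges.append(np.column_stack([members[iu], members[ju]]))
    e = np.concatenate(edges) if edges else np.empty((0, 2), dtype=np.int64)
    return PairGraph(
        n_nodes=n, edges=e, weights=np.ones(len(e)), method="kmeans",
        params={"n_clusters": n_clusters, "seed": seed},
    )


def hetero_graph(
    imsm: SimilarityMatrix, idsm: SimilarityMatrix, assoc: AssociationMatrix
) -> PairGraph:
    """Heterogeneous entity graph over miRNA and disease nodes.

    Nodes 0..n_m-1 are miRNAs, n_m..n_m+n_d-1 diseases.  The miRNA block and
    disease block are fully connected with similarity weights; the bipartite
    block holds the binary training associations.  Node features embed each
    entity's similarity row into a shared (n_m + n_d)-dimensional space.
    """
    if list(assoc.mirnas) != list(imsm.labels) or list(assoc.diseases) != list(idsm.labels):
        raise InputError("entity labels of assoc and similarity matrices differ")
    n_m, n_d = imsm.n, idsm.n
    edges, weights = [], []
    iu, ju = np.triu_indices(n_m, k=1)
    keep = imsm.values[iu, ju] > 0  # zero similarity carries no edge
    edges.append(np.column_stack([iu[keep], ju[keep]]))
    weights.append(imsm.values[iu[keep], ju[keep]])
    iu, ju = np.triu_indices(n_d, k=1)
    keep = idsm.values[iu, ju] > 0
    edges.append(np.column_stack([iu[keep] + n_m, ju[keep] + n_m]))
    weights.append(idsm.values[iu[keep], ju[keep]])
    ai, aj = np.nonzero(assoc.values)
    if len(ai):
        edges.append(np.column_stack([ai, aj + n_m]))
        weights.append(np.ones(len(ai)))
    e = np.concatenate(edges)
    w = np.concatenate(weights)
    feats = np.zeros((n_m + n_d, n_m + n_d))
    feats[:n_m, :n_m] = imsm.values
    feats[n_m:, n_m:] = idsm.values
    names = list(imsm.labels) + list(idsm.labels)
    return PairGraph(
        n_nodes=n_m + n_d, edges=e, weights=w, method="hetero",
        params={"n_mirna": n_m, "n_disease": n_d},
        node_features=feats, node_names=names,
    )
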