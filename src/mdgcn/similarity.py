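"""Similarity matrices used as node features for miRNA-disease pair nodes.

Four matrices feed the pipeline:

* MFSM — miRNA functional similarity, a best-match-average over the gene
  sets annotated to each miRNA, with gene-gene similarity read off a
  weighted gene interaction network.
* DSSM — disease semantic similarity. Two variants over the disease MeSH-style
  DAG are supported (shared-ancestor contribution decay, and an
  information-content variant), element-wise averaged into the final DSSM;
  precomputed matrices can be supplied instead.
* MGSM / DGSM — Gaussian interaction profile (GIP) kernels computed from the
  binary association matrix.
* IMSM / IDSM — the integrated matrices: functional/semantic where nonzero,
  GIP as fallback elsewhere.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputError",
    "SYMMETRY_TOL",
    "SimilarityMatrix",
    "AssociationMatrix",
    "GeneInteractionNetwork",
    "gene_similarity",
    "mirna_functional_similarity",
    "gip_kernel_similarity",
    "average_semantic_similarity",
    "integrate_similarity",
    "integrate_with_profile_kernel",
    "dag_semantic_similarity",
]

#: absolute tolerance for symmetry / zero checks on similarity matrices
SYMMETRY_TOL = 1e-12


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Labeled square matrix of pairwise similarity scores in [0, 1].

    Parameters
    ----------
    labels
        Ordered entity identifiers (miRNAs or diseases).
    values
        Square array, ``values[i, j]`` the similarity of ``labels[i]`` and
        ``labels[j]``.  Must be symmetric to within :data:`SYMMETRY_TOL`.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise InputError("duplicate labels in similarity matrix")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > 1e-8:
            raise InputError(f"similarity matrix asymmetric (max |M-M^T| = {asym:g})")
        if self.values.size and (self.values.min() < -SYMMETRY_TOL or self.values.max() > 1 + 1e-9):
            raise InputError("similarity values outside [0, 1]")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise InputError(f"unknown entity {label!r}") from None

    def row(self, label: str) -> np.ndarray:
        return self.values[self.loc(label)]

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.values[self.loc(i), self.loc(j)])

    def subset(self, labels: Iterable[str]) -> "SimilarityMatrix":
        """Restriction to a label subset, in the given order."""
        idx = np.array([self.loc(x) for x in labels])
        return SimilarityMatrix(labels=[self.labels[i] for i in idx],
                                values=self.values[np.ix_(idx, idx)])


@dataclass
class AssociationMatrix:
    """Binary miRNA × disease association matrix ``A``.

    Row ``i`` is the interaction profile of miRNA ``i``; column ``j`` (as a
    vector) is the interaction profile ``P(d_j)`` of disease ``j``.
    """

    mirnas: list[str]
    diseases: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.mirnas = [str(x) for x in self.mirnas]
        self.diseases = [str(x) for x in self.diseases]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise InputError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirnas)} miRNAs x {len(self.diseases)} diseases"
            )
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise InputError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self._mi = {m: i for i, m in enumerate(self.mirnas)}
        self._di = {d: j for j, d in enumerate(self.diseases)}
        if len(self._mi) != len(self.mirnas) or len(self._di) != len(self.diseases):
            raise InputError("duplicate entity labels in association matrix")

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def mirna_index(self, m: str) -> int:
        try:
            return self._mi[m]
        except KeyError:
            raise InputError(f"unknown miRNA {m!r}") from None

    def disease_index(self, d: str) -> int:
        try:
            return self._di[d]
        except KeyError:
            raise InputError(f"unknown disease {d!r}") from None

    def positive_pairs(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.values)
        return [(self.mirnas[i], self.diseases[j]) for i, j in zip(ii, jj)]


@dataclass
class GeneInteractionNetwork:
    """Weighted gene-gene interaction network.

    ``weights`` maps unordered gene pairs to a score in [0, 1]; pairs are
    stored with sorted keys so lookup is orientation-free.  Self-pairs are not
    stored — identity similarity is fixed at 1.
    """

    genes: list[str]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self._gene_set = set(self.genes)
        norm: dict[tuple[str, str], float] = {}
        for (a, b), w in self.weights.items():
            if a == b:
                raise InputError(f"self-edge on gene {a!r} not allowed")
            if a not in self._gene_set or b not in self._gene_set:
                missing = a if a not in self._gene_set else b
                raise InputError(f"edge references unknown gene {missing!r}")
            if not (0.0 <= w <= 1.0):
                raise InputError(f"edge weight {w} for ({a}, {b}) outside [0, 1]")
            norm[(a, b) if a < b else (b, a)] = float(w)
        self.weights = norm

    @classmethod
    def from_scored_edges(
        cls, edges: Iterable[tuple[str, str, float]]
    ) -> "GeneInteractionNetwork":
        """Build a network from raw (log-likelihood) scored edges.

        Scores are min-max normalized to [0, 1]; a constant-score network maps
        every weight to 1 so that degenerate inputs stay deterministic.
        """
        edges = [(str(a), str(b), float(s)) for a, b, s in edges]
        if not edges:
            raise InputError("empty edge list")
        scores = np.array([s for _, _, s in edges])
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            w = (scores - lo) / (hi - lo)
        else:
            w = np.ones_like(scores)
        genes: list[str] = []
        seen: set[str] = set()
        for a, b, _ in edges:
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        weights = {(a, b): float(wi) for (a, b, _), wi in zip(edges, w)}
        return cls(genes=genes, weights=weights)

    def has_gene(self, g: str) -> bool:
        return g in self._gene_set


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------


def gene_similarity(network: GeneInteractionNetwork, g_i: str, g_j: str) -> float:
    """Pairwise gene functional similarity S(g_i, g_j).

    Returns 1 for identical genes, the normalized edge weight where an edge
    exists, and 0 otherwise.
    """
    for g in (g_i, g_j):
        if not network.has_gene(g):
            raise InputError(f"unknown gene {g!r}")
    if g_i == g_j:
        return 1.0
    key = (g_i, g_j) if g_i < g_j else (g_j, g_i)
    return network.weights.get(key, 0.0)


def mirna_functional_similarity(
    network: GeneInteractionNetwork, gene_sets: Mapping[str, Iterable[str]]
) -> SimilarityMatrix:
    """Best-match-average miRNA functional similarity (MFSM).

    For miRNAs with gene sets ``G_i`` and ``G_j``::

        MFSM(i, j) = ( sum_{g in G_i} max_{t in G_j} S(g, t)
                     + sum_{g in G_j} max_{t in G_i} S(g, t) ) / (|G_i| + |G_j|)

    The diagonal is exactly 1 because every gene best-matches itself.
    """
    mirnas = list(gene_sets)
    sets: list[list[str]] = []
    for m in mirnas:
        gs = sorted(set(map(str, gene_sets[m])))
        if not gs:
            raise InputError(f"miRNA {m!r} has an empty gene set")
        for g in gs:
            if not network.has_gene(g):
                raise InputError(f"gene {g!r} of miRNA {m!r} unknown to the network")
        sets.append(gs)

    # gene-level similarity cache over the genes actually used
    used = sorted({g for gs in sets for g in gs})
    gi = {g: k for k, g in enumerate(used)}
    S = np.zeros((len(used), len(used)))
    for a in used:
        for b in used:
            S[gi[a], gi[b]] = gene_similarity(network, a, b)

    idx = [[gi[g] for g in gs] for gs in sets]
    n = len(mirnas)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i):
            block = S[np.ix_(idx[i], idx[j])]
            num = block.max(axis=1).sum() + block.max(axis=0).sum()
            out[i, j] = out[j, i] = num / (len(idx[i]) + len(idx[j]))
    return SimilarityMatrix(labels=mirnas, values=out)


# ---------------------------------------------------------------------------
# GIP kernel similarity
# ---------------------------------------------------------------------------


def gip_kernel_similarity(
    assoc: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over association profiles.

    For diseases (``axis="disease"``) the profile of disease ``d_i`` is the
    binary column of the association matrix, and::

        DGSM(i, j) = exp(-gamma * ||P(d_i) - P(d_j)||^2)
        gamma = gamma_prime / mean_i ||P(d_i)||^2

    where the mean runs over the profiles being compared.  ``axis="mirna"``
    applies the same kernel to rows (MGSM).

    Raises
    ------
    InputError
        If every profile is zero (the bandwidth is undefined); callers fall
        back to the semantic/functional matrix alone.
    """
    if axis == "disease":
        profiles = assoc.values.T.astype(float)
        labels = assoc.diseases
    elif axis == "mirna":
        profiles = assoc.values.astype(float)
        labels = assoc.mirnas
    else:
        raise InputError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    if gamma_prime < 0:
        raise InputError("gamma_prime must be nonnegative")
    sq = (profiles**2).sum(axis=1)
    mean_sq = sq.mean() if sq.size else 0.0
    if mean_sq == 0:
        raise InputError("all interaction profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    # ||x - y||^2 via the Gram expansion; profiles are binary so this is exact
    gram = profiles @ profiles.T
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    k = np.exp(-gamma * d2)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(labels=list(labels), values=k)


# ---------------------------------------------------------------------------
# semantic similarity: averaging and the optional DAG builders
# ---------------------------------------------------------------------------


def average_semantic_similarity(
    dssm1: SimilarityMatrix, dssm2: SimilarityMatrix
) -> SimilarityMatrix:
    """Element-wise mean of two semantic similarity matrices."""
    if dssm1.labels != dssm2.labels:
        raise InputError("semantic similarity matrices have different labels")
    return SimilarityMatrix(
        labels=list(dssm1.labels), values=(dssm1.values + dssm2.values) / 2.0
    )


def integrate_similarity(
    primary: SimilarityMatrix, gip: SimilarityMatrix
) -> SimilarityMatrix:
    """Fuse a functional/semantic matrix with its GIP kernel counterpart.

    Keeps the primary score wherever it is nonzero and substitutes the GIP
    score in the zero cells, so sparse curated similarities are densified by
    the association-profile kernel.
    """
    if primary.labels != gip.labels:
        raise InputError("integration requires identical label order")
    out = np.where(np.abs(primary.values) > SYMMETRY_TOL, primary.values, gip.values)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(labels=list(primary.labels), values=out)


def integrate_with_profile_kernel(
    sim: SimilarityMatrix,
    train_assoc: AssociationMatrix,
    axis: str,
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Integrate a full-registry similarity matrix with a training-data GIP kernel.

    The GIP kernel is computed only from the training association matrix, so
    entities absent from it ("new" miRNAs/diseases) have no profile: their
    rows keep the functional/semantic similarity alone, with zeros where that
    too is missing.  For entities present in training, zero cells are filled
    from the kernel as in :func:`integrate_similarity`.  This is the
    no-leakage path used when test entities sit in the graph label-masked.
    """
    labels = sim.labels
    train_labels = train_assoc.mirnas if axis == "mirna" else train_assoc.diseases
    missing = [x for x in train_labels if x not in sim._index]
    if missing:
        raise InputError(f"training entity {missing[0]!r} absent from similarity matrix")
    try:
        gip = gip_kernel_similarity(train_assoc, axis, gamma_prime)
    except InputError:
        # all-zero profiles: no kernel information, keep the primary matrix
        return SimilarityMatrix(labels=list(labels), values=sim.values.copy())
    out = sim.values.copy()
    idx = np.array([sim.loc(x) for x in train_labels])
    sub = out[np.ix_(idx, idx)]
    filled = np.where(np.abs(sub) > SYMMETRY_TOL, sub, gip.values)
    out[np.ix_(idx, idx)] = filled
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(labels=list(labels), values=out)


def _dag_contributions(
    term: str, parents: Mapping[str, Iterable[str]], decay: float
) -> dict[str, float]:
    """Decayed ancestor contributions D_term(t) for every t in term's DAG."""
    contrib = {term: 1.0}
    queue = [term]
    while queue:
        t = queue.pop()
        for p in parents.get(t, ()):  # walk child -> parent
            cand = contrib[t] * decay
            if cand > contrib.get(p, 0.0):
                contrib[p] = cand
                queue.append(p)
    return contrib


def dag_semantic_similarity(
    diseases: list[str],
    parents: Mapping[str, Iterable[str]],
    *,
    decay: float = 0.5,
    variant: str = "decay",
) -> SimilarityMatrix:
    """Reference DAG-based disease semantic similarity builder.

    Two variants over a child→parents disease hierarchy:

    * ``"decay"`` — a term contributes 1 to its own disease and its
      contribution decays by ``decay`` per edge walking up the DAG; the
      similarity of two diseases is the shared contribution mass over the
      total (diseases sharing more of their DAGs are more similar).
    * ``"ic"`` — contributions are information-content weights
      ``-log(fraction of disease DAGs containing the term)``, so rare
      (specific) terms dominate.

    Both variants yield values in [0, 1] with unit diagonal.  This builder is
    a convenience for running the pipeline end to end from a raw hierarchy;
    precomputed semantic matrices can be supplied instead.
    """
    if variant not in ("decay", "ic"):
        raise InputError(f"unknown variant {variant!r}")
    if not 0 < decay <= 1:
        raise InputError("decay must be in (0, 1]")
    contribs = {d: _dag_contributions(d, parents, decay) for d in diseases}
    if variant == "ic":
        n = len(diseases)
        counts: dict[str, int] = {}
        for c in contribs.values():
            for t in c:
                counts[t] = counts.get(t, 0) + 1
        ic = {t: -math.log(counts[t] / n) for t in counts}
        contribs = {
            d: {t: ic[t] for t in c} for d, c in contribs.items()
        }
    out = np.eye(len(diseases))
    for i, a in enumerate(diseases):
        ca, va = contribs[a], sum(contribs[a].values())
        for j in range(i):
            b = diseases[j]
            cb, vb = contribs[b], sum(contribs[b].values())
            shared = set(ca) & set(cb)
            denom = va + vb
            s = sum(ca[t] + cb[t] for t in shared) / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = min(s, 1.0)
    return SimilarityMatrix(labels=list(diseases), values=out)
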