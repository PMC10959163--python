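"""Task splits, metrics, repeated experiments and candidate ranking.

The four association-novelty regimes route each held-out association by the
novelty of its two entities:

* Tp — known miRNA, known disease (new link between old entities);
* Td — known miRNA, new disease;
* Tm — new miRNA, known disease;
* Tn — new miRNA, new disease.

Training always uses the old-entity associations; test pairs join the graph
as label-masked nodes.  Per-task negatives are count-matched and drawn from
unknown pairs inside the same entity regime as the task's positives, so no
regime leaks into another.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gcn import GCNConfig, TrainedModel, predict_scores, train
from .pair_graph import (
    MDPNodeTable,
    PairGraph,
    build_mdp_nodes,
    kmeans_graph,
    knn_regular_graph,
)
from .sampler import edge_probabilities, estimate_normalization
from .similarity import (
    AssociationMatrix,
    InputError,
    SimilarityMatrix,
    integrate_with_profile_kernel,
)

__all__ = [
    "TASKS",
    "TaskSplit",
    "MetricsReport",
    "MDADataset",
    "ExperimentConfig",
    "make_task_splits",
    "compute_metrics",
    "repeat_experiment",
    "run_task",
    "run_task_repeated",
    "rank_candidates",
    "paired_ttest",
    "auc_score",
]

TASKS = ("tp", "td", "tm", "tn")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass
class TaskSplit:
    """Training pairs plus the four labeled test sets."""

    train_pairs: list[tuple[str, str]]
    tasks: dict[str, list[tuple[str, str, int]]]
    old_mirnas: list[str]
    old_diseases: list[str]
    new_mirnas: list[str]
    new_diseases: list[str]


def _sample_regime_negatives(
    mirnas: Sequence[str],
    diseases: Sequence[str],
    count: int,
    forbidden: set[tuple[str, str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Uniform unknown pairs from a mirna x disease regime, without replacement."""
    n_m, n_d = len(mirnas), len(diseases)
    total = n_m * n_d
    avail = total - sum(1 for (m, d) in forbidden if m in set(mirnas) and d in set(diseases))
    if count > max(avail, 0):
        raise InputError(
            f"cannot draw {count} negatives from a regime with ~{avail} unknown pairs"
        )
    chosen: list[tuple[str, str]] = []
    seen = set(forbidden)
    # rejection sampling; regimes are sparse in positives so this terminates fast
    while len(chosen) < count:
        draw = rng.integers(0, total, size=2 * (count - len(chosen)) + 8)
        for f in draw:
            pair = (mirnas[f // n_d], diseases[f % n_d])
            if pair not in seen:
                seen.add(pair)
                chosen.append(pair)
                if len(chosen) == count:
                    break
    return chosen


def make_task_splits(
    old_assoc: Iterable[tuple[str, str]],
    new_assoc: Iterable[tuple[str, str]],
    old_mirnas: Sequence[str],
    old_diseases: Sequence[str],
    new_mirnas: Sequence[str] | None = None,
    new_diseases: Sequence[str] | None = None,
    seed: int = 0,
) -> TaskSplit:
    """Route each new association into exactly one of Tp/Td/Tm/Tn.

    ``new_mirnas``/``new_diseases`` default to the new-association entities
    absent from the old registries.  Per-task negatives are sampled from
    unknown pairs of the task's own entity regime, count-matched to its
    positives, disjoint from every positive association.
    """
    old_assoc = [(str(m), str(d)) for m, d in old_assoc]
    new_assoc = [(str(m), str(d)) for m, d in new_assoc]
    old_m, old_d = set(map(str, old_mirnas)), set(map(str, old_diseases))
    for m, d in old_assoc:
        if m not in old_m:
            raise InputError(f"old association references unregistered miRNA {m!r}")
        if d not in old_d:
            raise InputError(f"old association references unregistered disease {d!r}")

    if new_mirnas is None:
        new_mirnas = sorted({m for m, _ in new_assoc if m not in old_m})
    if new_diseases is None:
        new_diseases = sorted({d for _, d in new_assoc if d not in old_d})
    new_m, new_d = set(new_mirnas), set(new_diseases)

    routed: dict[str, list[tuple[str, str, int]]] = {t: [] for t in TASKS}
    for m, d in new_assoc:
        key = ("tm" if m in new_m else "tp") if d not in new_d else ("tn" if m in new_m else "td")
        routed[key].append((m, d, 1))

    all_pos = set(old_assoc) | set(new_assoc)
    regimes = {
        "tp": (sorted(old_m), sorted(old_d)),
        "td": (sorted(old_m), sorted(new_d)),
        "tm": (sorted(new_m), sorted(old_d)),
        "tn": (sorted(new_m), sorted(new_d)),
    }
    rng = np.random.default_rng(seed)
    for t in TASKS:
        n_pos = len(routed[t])
        if n_pos == 0:
            continue
        ms, ds = regimes[t]
        negs = _sample_regime_negatives(ms, ds, n_pos, all_pos, rng)
        routed[t].extend((m, d, 0) for m, d in negs)

    return TaskSplit(
        train_pairs=old_assoc,
        tasks=routed,
        old_mirnas=sorted(old_m),
        old_diseases=sorted(old_d),
        new_mirnas=sorted(new_m),
        new_diseases=sorted(new_d),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 at the threshold, plus rank AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise InputError("scores and labels differ in length")
    pred = scores >= threshold
    actual = labels == 1
    tp = int((pred & actual).sum())
    fp = int((pred & ~actual).sum())
    fn = int((~pred & actual).sum())
    tn = int((~pred & ~actual).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / len(labels),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": auc_score(scores, labels),
    }


@dataclass
class MetricsReport:
    """Per-repetition metric values with their mean and standard deviation."""

    per_run: pd.DataFrame  # columns: run, seed, then one column per metric

    @property
    def METRICS(self) -> tuple[str, ...]:
        return tuple(c for c in self.per_run.columns if c not in ("run", "seed"))

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_run[m].mean()) for m in self.METRICS}

    @property
    def sd(self) -> dict[str, float]:
        return {m: float(self.per_run[m].std(ddof=0)) for m in self.METRICS}

    @property
    def n_repeats(self) -> int:
        return len(self.per_run)

    def summary(self) -> str:
        lines = [f"repetitions\t{self.n_repeats}"]
        for m in self.METRICS:
            lines.append(f"{m}\t{self.mean[m]:.4f} +/- {self.sd[m]:.4f}")
        return "\n".join(lines)


def repeat_experiment(
    run_fn: Callable[[int], dict[str, float]],
    n_repeats: int = 10,
    base_seed: int = 0,
) -> MetricsReport:
    """Run ``run_fn(seed)`` for seeds base..base+n-1 and aggregate metrics."""
    if n_repeats < 1:
        raise InputError("n_repeats must be >= 1")
    rows = []
    for r in range(n_repeats):
        seed = base_seed + r
        metrics = run_fn(seed)
        rows.append({"run": r, "seed": seed, **metrics})
    return MetricsReport(per_run=pd.DataFrame(rows))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on per-run metric values; returns (t, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("need two aligned vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------


@dataclass
class MDADataset:
    """Everything an experiment needs: full-registry similarities + pairs."""

    mirna_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    split: TaskSplit


@dataclass
class ExperimentConfig:
    """One experimental condition (graph architecture x sampler switch)."""

    graph_method: str = "regular"       # "regular" | "kmeans"
    k: int = 5
    n_clusters: int = 300
    metric: str = "euclidean"
    use_sampler: bool = True
    n_presample: int = 50               # N trial subgraphs for alpha/lambda
    negative_ratio: float = 1.0
    gcn: GCNConfig = field(default_factory=GCNConfig)


def _training_association_matrix(split: TaskSplit) -> AssociationMatrix:
    mirnas = split.old_mirnas
    diseases = split.old_diseases
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    a = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for m, d in split.train_pairs:
        a[mi[m], di[d]] = 1
    return AssociationMatrix(mirnas=mirnas, diseases=diseases, values=a)


def _assemble_nodes(
    dataset: MDADataset,
    task: str,
    seed: int,
    negative_ratio: float,
) -> MDPNodeTable:
    """Train + label-masked test nodes with integrated-similarity features."""
    split = dataset.split
    train_assoc = _training_association_matrix(split)
    imsm = integrate_with_profile_kernel(dataset.mirna_sim, train_assoc, "mirna")
    idsm = integrate_with_profile_kernel(dataset.disease_sim, train_assoc, "disease")

    test_pairs = split.tasks.get(task, [])
    if not test_pairs:
        raise InputError(f"task {task!r} has no test pairs")
    forbidden = set(split.train_pairs)
    forbidden.update((m, d) for t in TASKS for m, d, _ in split.tasks.get(t, []))
    rng = np.random.default_rng(seed)
    n_neg = int(round(negative_ratio * len(split.train_pairs)))
    train_negs = _sample_regime_negatives(
        split.old_mirnas, split.old_diseases, n_neg, forbidden, rng
    )

    pairs = [(m, d, 1, "train") for m, d in split.train_pairs]
    pairs += [(m, d, 0, "train") for m, d in train_negs]
    pairs += [(m, d, lab, "test-masked") for m, d, lab in test_pairs]
    return build_mdp_nodes(pairs, imsm, idsm)


def _build_graph(nodes: MDPNodeTable, config: ExperimentConfig, seed: int) -> PairGraph:
    if config.graph_method == "regular":
        return knn_regular_graph(nodes, k=config.k, metric=config.metric)
    if config.graph_method == "kmeans":
        return kmeans_graph(nodes, n_clusters=config.n_clusters, seed=seed)
    raise InputError(
        f"graph method {config.graph_method!r} not supported for MDP-node "
        "experiments (use 'regular' or 'kmeans')"
    )


def run_task(
    dataset: MDADataset,
    task: str,
    config: ExperimentConfig,
    seed: int,
    return_extras: bool = False,
):
    """One full pipeline run on one task; returns the metric dict.

    Fresh negative sampling, graph, sampler estimation and model init per
    seed.  With ``return_extras`` the trained model, graph, node table and
    test scores are returned alongside for ranking or inspection.
    """
    nodes = _assemble_nodes(dataset, task, seed, config.negative_ratio)
    graph = _build_graph(nodes, config, seed)
    sampler = None
    if config.use_sampler:
        probs = edge_probabilities(graph)
        m_edges = config.gcn.edges_per_batch or max(
            1, graph.n_edges // config.gcn.batches_per_epoch
        )
        coeffs = estimate_normalization(
            graph, probs, m_edges, config.n_presample, seed=seed + 1
        )
        sampler = (probs, coeffs)
    model = train(config.gcn, graph, nodes, sampler=sampler, seed=seed)
    mask = nodes.roles == "test-masked"
    scores = predict_scores(model, graph, nodes)[mask]
    labels = nodes.labels[mask]
    metrics = compute_metrics(scores, labels)
    if return_extras:
        return metrics, {
            "model": model, "graph": graph, "nodes": nodes,
            "scores": scores, "labels": labels,
        }
    return metrics


def run_task_repeated(
    dataset: MDADataset,
    task: str,
    config: ExperimentConfig,
    n_repeats: int = 10,
    base_seed: int = 0,
) -> MetricsReport:
    """Repeat :func:`run_task` with consecutive seeds and aggregate."""
    return repeat_experiment(
        lambda s: run_task(dataset, task, config, seed=s),
        n_repeats=n_repeats,
        base_seed=base_seed,
    )


# ---------------------------------------------------------------------------
# case-study ranking
# ---------------------------------------------------------------------------


def rank_candidates(
    model: TrainedModel,
    graph: PairGraph,
    nodes: MDPNodeTable,
    disease: str,
    candidate_mirnas: Sequence[str] | None = None,
    top_k: int = 30,
) -> list[tuple[str, float]]:
    """Rank candidate miRNAs for one disease by predicted association score.

    Scores every node of the table pairing ``disease`` with a candidate miRNA,
    excluding known training positives; descending score, ties broken by
    miRNA label.  Candidate pairs must be present in the node table (add them
    as label-masked nodes when assembling the graph).
    """
    table = nodes.table
    if disease not in set(table["disease"]):
        raise InputError(f"unknown disease {disease!r}")
    sel = table["disease"] == disease
    if candidate_mirnas is not None:
        sel &= table["mirna"].isin(set(map(str, candidate_mirnas)))
    # exclude known training positives from the candidate ranking
    sel &= ~((table["role"] == "train") & (table["label"] == 1))
    idx = table.index[sel].to_numpy()
    if not len(idx):
        return []
    scores = predict_scores(model, graph, nodes, node_ids=idx)
    order = sorted(
        zip(scores.tolist(), table.loc[idx, "mirna"].tolist()),
        key=lambda t: (-t[0], t[1]),
    )
    return [(m, s) for s, m in order[:top_k]]
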