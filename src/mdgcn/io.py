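"""Readers and writers for the interchange formats, plus run configuration.

All files are UTF-8, tab-delimited, decimal point '.', no index columns, so
fixtures stay bit-comparable across platforms.  Floats are written with
``repr``-faithful precision and every writer drops a ``<file>.meta.json``
sidecar carrying the seed and a hash of the producing configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import MDADataset, MetricsReport, TaskSplit
from .pair_graph import MDPNodeTable, PairGraph
from .similarity import AssociationMatrix, InputError, SimilarityMatrix

logger = logging.getLogger("mdgcn")

__all__ = [
    "RunConfig",
    "load_config",
    "read_association_list",
    "write_association_list",
    "read_pair_list",
    "write_pair_list",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_gene_network_edges",
    "read_gene_sets",
    "write_graph",
    "read_registry",
    "write_registry",
    "write_metrics_report",
    "write_ranked_list",
    "load_dataset",
    "write_sidecar",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat run configuration mirroring the YAML config file.

    With ``synthetic`` true the dataset is generated in memory from the
    generator settings; otherwise the four input paths must point to files
    produced by ``mdgcn simulate`` or prepared in the same formats.
    """

    synthetic: bool = True
    train_pairs: str | None = None
    new_pairs: str | None = None
    mirna_similarity: str | None = None
    disease_similarity: str | None = None
    registry: str | None = None
    # generator settings (used when synthetic)
    n_mirna: int = 200
    n_disease: int = 150
    n_blocks: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    similarity_signal: float = 0.8
    noise_sd: float = 0.05
    # experiment settings
    graph_method: str = "regular"
    k: int = 5
    n_clusters: int = 300
    metric: str = "euclidean"
    use_sampler: bool = True
    n_presample: int = 50
    negative_ratio: float = 1.0
    tasks: list[str] = field(default_factory=lambda: ["tp"])
    n_repeats: int = 10
    # GCN settings
    hidden: list[int] = field(default_factory=lambda: [128, 64])
    activation: str = "relu"
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 200
    batches_per_epoch: int = 20
    lambda_cap: float = 10.0

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def experiment_config(self):
        from .evaluation import ExperimentConfig
        from .gcn import GCNConfig

        return ExperimentConfig(
            graph_method=self.graph_method,
            k=self.k,
            n_clusters=self.n_clusters,
            metric=self.metric,
            use_sampler=self.use_sampler,
            n_presample=self.n_presample,
            negative_ratio=self.negative_ratio,
            gcn=GCNConfig(
                hidden=tuple(self.hidden),
                activation=self.activation,
                dropout=self.dropout,
                learning_rate=self.learning_rate,
                weight_decay=self.weight_decay,
                epochs=self.epochs,
                batches_per_epoch=self.batches_per_epoch,
                lambda_cap=self.lambda_cap,
            ),
        )


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_sidecar(path: str | Path, seed: int | None, config: RunConfig | None) -> None:
    meta = {"seed": seed, "config_hash": config.hash() if config else None}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# association / pair lists
# ---------------------------------------------------------------------------


def _parse_lines(path: str | Path, n_min: int, n_max: int):
    lines = Path(path).read_text().splitlines()
    rows = []
    for no, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if not n_min <= len(parts) <= n_max:
            raise InputError(
                f"{path}:{no}: expected {n_min}-{n_max} tab-separated fields, "
                f"got {len(parts)}"
            )
        rows.append((no, parts))
    if not rows:
        raise InputError(f"{path}: no data lines")
    return rows


def read_association_list(path: str | Path) -> AssociationMatrix:
    """Two/three-column (miRNA, disease[, label]) list -> binary matrix.

    Duplicate pairs collapse to one entry with a logged warning; entity order
    is first-appearance order.
    """
    rows = _parse_lines(path, 2, 3)
    mirnas: list[str] = []
    diseases: list[str] = []
    mi: dict[str, int] = {}
    di: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    entries: list[tuple[int, int]] = []
    for no, parts in rows:
        m, d = parts[0], parts[1]
        if len(parts) == 3:
            if parts[2] not in ("0", "1"):
                raise InputError(f"{path}:{no}: label must be 0 or 1, got {parts[2]!r}")
            if parts[2] == "0":
                continue
        if (m, d) in seen:
            logger.warning("%s:%d: duplicate pair (%s, %s) collapsed", path, no, m, d)
            continue
        seen.add((m, d))
        if m not in mi:
            mi[m] = len(mirnas)
            mirnas.append(m)
        if d not in di:
            di[d] = len(diseases)
            diseases.append(d)
        entries.append((mi[m], di[d]))
    a = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for i, j in entries:
        a[i, j] = 1
    return AssociationMatrix(mirnas=mirnas, diseases=diseases, values=a)


def write_association_list(path: str | Path, pairs) -> None:
    with open(path, "w") as fh:
        for m, d in pairs:
            fh.write(f"{m}\t{d}\n")


def read_pair_list(path: str | Path) -> list[tuple[str, str, int]]:
    """Three-column (miRNA, disease, label) list."""
    rows = _parse_lines(path, 3, 3)
    out = []
    for no, (m, d, lab) in ((no, p) for no, p in rows):
        if lab not in ("0", "1"):
            raise InputError(f"{path}:{no}: label must be 0 or 1, got {lab!r}")
        out.append((m, d, int(lab)))
    return out


def write_pair_list(path: str | Path, pairs) -> None:
    with open(path, "w") as fh:
        for m, d, lab in pairs:
            fh.write(f"{m}\t{d}\t{lab}\n")


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Labeled square TSV; header row and first column both carry labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    labels = [str(x) for x in df.columns]
    row_labels = [str(x) for x in df.index]
    if labels != row_labels:
        raise InputError(f"{path}: header and row labels differ")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise InputError(f"{path}: matrix is not square: {values.shape}")
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad):
        i, j = bad[0]
        raise InputError(
            f"{path}: value {values[i, j]!r} at ({labels[i]}, {labels[j]}) "
            "outside [0, 1]"
        )
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > 1e-8:
        raise InputError(f"{path}: matrix asymmetric (max deviation {asym:g})")
    return SimilarityMatrix(labels=labels, values=values)


def write_similarity_matrix(path: str | Path, sim: SimilarityMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(sim.labels) + "\n")
        for lab, row in zip(sim.labels, sim.values):
            cells = "\t".join(_FLOAT_FMT % v for v in row)
            fh.write(f"{lab}\t{cells}\n")


# ---------------------------------------------------------------------------
# gene network / gene sets
# ---------------------------------------------------------------------------


def read_gene_network_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Three-column (gene, gene, raw log-likelihood score) edge list."""
    rows = _parse_lines(path, 3, 3)
    out = []
    for no, (a, b, s) in ((no, p) for no, p in rows):
        try:
            out.append((a, b, float(s)))
        except ValueError:
            raise InputError(f"{path}:{no}: non-numeric score {s!r}") from None
    return out


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column (miRNA, gene) list -> miRNA -> gene set map."""
    rows = _parse_lines(path, 2, 2)
    out: dict[str, set[str]] = {}
    for _, (m, g) in rows:
        out.setdefault(m, set()).add(g)
    return out


# ---------------------------------------------------------------------------
# graphs, registries, reports
# ---------------------------------------------------------------------------


def write_graph(edge_path: str | Path, node_path: str | Path,
                graph: PairGraph, nodes: MDPNodeTable | None = None) -> None:
    with open(edge_path, "w") as fh:
        for (u, v), w in zip(graph.edges, graph.weights):
            fh.write(f"{u}\t{v}\t{_FLOAT_FMT % w}\n")
    with open(node_path, "w") as fh:
        if nodes is not None:
            fh.write("node_id\tmirna\tdisease\tlabel\trole\n")
            for row in nodes.table.itertuples(index=False):
                fh.write(f"{row.node_id}\t{row.mirna}\t{row.disease}\t"
                         f"{row.label}\t{row.role}\n")
        elif graph.node_names is not None:
            fh.write("node_id\tname\n")
            for i, name in enumerate(graph.node_names):
                fh.write(f"{i}\t{name}\n")
        else:
            fh.write("node_id\n")
            for i in range(graph.n_nodes):
                fh.write(f"{i}\n")


def write_registry(path: str | Path, split: TaskSplit) -> None:
    with open(path, "w") as fh:
        fh.write("entity\tkind\tstatus\n")
        for m in split.old_mirnas:
            fh.write(f"{m}\tmirna\told\n")
        for m in split.new_mirnas:
            fh.write(f"{m}\tmirna\tnew\n")
        for d in split.old_diseases:
            fh.write(f"{d}\tdisease\told\n")
        for d in split.new_diseases:
            fh.write(f"{d}\tdisease\tnew\n")


def read_registry(path: str | Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"entity", "kind", "status"}
    if not need.issubset(df.columns):
        raise InputError(f"{path}: registry needs columns {sorted(need)}")
    sel = lambda k, s: df.loc[(df["kind"] == k) & (df["status"] == s), "entity"].tolist()
    return {
        "old_mirnas": sel("mirna", "old"),
        "new_mirnas": sel("mirna", "new"),
        "old_diseases": sel("disease", "old"),
        "new_diseases": sel("disease", "new"),
    }


def write_metrics_report(path: str | Path, report: MetricsReport) -> None:
    """Key-value summary plus one row per repetition (machine-readable)."""
    with open(path, "w") as fh:
        fh.write(report.summary() + "\n")
    table_path = Path(str(path)).with_suffix(".runs.tsv")
    report.per_run.to_csv(table_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_ranked_list(path: str | Path, disease: str,
                      ranked: list[tuple[str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tmirna\tdisease\tscore\n")
        for r, (m, s) in enumerate(ranked, start=1):
            fh.write(f"{r}\t{m}\t{disease}\t{_FLOAT_FMT % s}\n")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def load_dataset(config: RunConfig, seed: int) -> MDADataset:
    """Materialise the dataset a run works on (synthetic or from files)."""
    from .evaluation import make_task_splits
    from .synthetic import SyntheticSpec, generate

    if config.synthetic:
        data = generate(SyntheticSpec(
            n_mirna=config.n_mirna,
            n_disease=config.n_disease,
            n_blocks=config.n_blocks,
            p_in=config.p_in,
            p_out=config.p_out,
            similarity_signal=config.similarity_signal,
            noise_sd=config.noise_sd,
            seed=seed,
        ))
        split = make_task_splits(
            data.old_pairs, data.new_pairs,
            data.old_mirnas, data.old_diseases,
            data.new_mirnas, data.new_diseases,
            seed=seed,
        )
        return MDADataset(mirna_sim=data.mirna_sim,
                          disease_sim=data.disease_sim, split=split)

    for key in ("train_pairs", "new_pairs", "mirna_similarity", "disease_similarity"):
        if getattr(config, key) is None:
            raise InputError(f"config key {key!r} required when synthetic is false")
    mirna_sim = read_similarity_matrix(config.mirna_similarity)
    disease_sim = read_similarity_matrix(config.disease_similarity)
    train_assoc = read_association_list(config.train_pairs)
    new_assoc = read_association_list(config.new_pairs)
    if config.registry:
        reg = read_registry(config.registry)
        old_m, old_d = reg["old_mirnas"], reg["old_diseases"]
        new_m, new_d = reg["new_mirnas"], reg["new_diseases"]
    else:
        old_m, old_d = train_assoc.mirnas, train_assoc.diseases
        new_m = new_d = None
    split = make_task_splits(
        train_assoc.positive_pairs(), new_assoc.positive_pairs(),
        old_m, old_d, new_m, new_d, seed=seed,
    )
    return MDADataset(mirna_sim=mirna_sim, disease_sim=disease_sim, split=split)
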