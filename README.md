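# mdgcn

Prediction of miRNA–disease associations (MDAs) with a graph convolutional
network built on an **exactly k-regular** graph of miRNA–disease pairs, trained
with a degree-weighted **random edge sampler**.

Most experimentally confirmed miRNA–disease links come from slow, costly
bench work, so computational ranking of candidate links is used to prioritise
validation. `mdgcn` recasts link prediction as transductive node
classification: every candidate pair (m, d) becomes one node whose feature
vector concatenates the miRNA's integrated-similarity row and the disease's
integrated-similarity row, and a GCN classifies nodes as associated or not.
The package is aimed at computational biologists studying network-based
association inference, and at anyone interested in how the *regularity* of
the constructed graph affects GCN behaviour.

## The model

**Node features.** Two similarity sources per entity type are fused:

* miRNA functional similarity (MFSM), a best-match average over the gene
  sets G_i annotated to each miRNA,

  `MFSM(i, j) = ( Σ_{g∈G_i} max_{t∈G_j} S(g,t) + Σ_{g∈G_j} max_{t∈G_i} S(g,t) ) / (|G_i| + |G_j|)`,

  with gene–gene similarity S read from a min-max-normalised weighted
  interaction network; disease semantic similarity (DSSM) from a MeSH-style
  DAG (two variants, element-wise averaged), or supplied precomputed.
* Gaussian interaction profile (GIP) kernels on the binary association
  matrix A: `DGSM(i, j) = exp(−γ_d ‖P(d_i) − P(d_j)‖²)` with
  `γ_d = γ'_d / mean_i ‖P(d_i)‖²`, and MGSM likewise on rows.

Integration keeps the curated score where it is nonzero and falls back to
the GIP kernel elsewhere, giving IMSM and IDSM.

**Graph.** Pair nodes are wired by mutual k-nearest neighbours on their
features; a deterministic repair pass then brings every node to degree
exactly k (default k = 5), so the degree matrix is `diag(k, …, k)`. Two
contrast architectures are provided: a non-regular homogeneous graph from
k-means cliques, and a heterogeneous entity graph (similarity blocks +
bipartite association block).

**GCN.** Propagation follows the renormalised rule
`H^{l+1} = σ(D̃^{−1/2} (A + I) D̃^{−1/2} H^l W^l)` with a dense head to one
sigmoid logit. Training draws minibatches by sampling M edges with
replacement, edge (u, v) with probability
`p(e_{u,v}) ∝ 1/deg(u) + 1/deg(v)` (uniform on a regular graph), and
de-biases the induced-subgraph loss and aggregation with empirical
coefficients `λ_v = C_v/N` and `α_{u,v} = C_{u,v}/C_v` estimated from N
trial subgraphs.

**Evaluation.** Held-out associations are routed into four novelty regimes —
Tp (known miRNA, known disease), Td (new disease), Tm (new miRNA), Tn (both
new) — with count-matched negatives from the same entity regime; accuracy,
precision, recall, F1 and rank-statistic AUC are reported over repeated
runs, with a paired t-test between configurations.

## Worked example

The synthetic generator plants block structure: entities carry latent
blocks, matched-block pairs associate at `p_in`, mismatched at `p_out`, and
similarities are noisy block indicators — so the features genuinely carry
the association signal.

```python
from mdgcn.io import RunConfig, load_dataset
from mdgcn.evaluation import run_task_repeated

cfg = RunConfig(n_mirna=100, n_disease=80, epochs=60)
dataset = load_dataset(cfg, seed=7)
report = run_task_repeated(dataset, "tp", cfg.experiment_config(),
                           n_repeats=3, base_seed=7)
print(report.summary())
```

prints

```
repetitions	3
accuracy	0.7884 +/- 0.0161
precision	0.8012 +/- 0.0213
recall	0.7678 +/- 0.0191
f1	0.7839 +/- 0.0162
auc	0.8018 +/- 0.0110
```

i.e. on a 100×80 planted dataset the pipeline recovers held-out Tp links
with mean AUC ≈ 0.80 over three repetitions (each repetition resamples
negatives and reinitialises the model). Under these generator settings the
only learnable signal is block membership, and an oracle that knows the true
blocks scores ≈ 0.82 here — the model operates close to that ceiling.

The same protocol is available from the shell:

```sh
mdgcn run-all --seed 7 --config my_run.yaml --out results/
mdgcn rank --disease disease-005 --seed 7 --out results/ --top-k 30
```

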