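"""Task splits, metrics, repeated runs, paired tests and ranking."""

import numpy as np
import pytest
from scipy import stats

from mdgcn.evaluation import (
    ExperimentConfig,
    auc_score,
    compute_metrics,
    make_task_splits,
    paired_ttest,
    rank_candidates,
    repeat_experiment,
    run_task,
)
from mdgcn.gcn import GCNConfig
from mdgcn.io import RunConfig, load_dataset
from mdgcn.similarity import InputError


class TestTaskSplits:
    def test_four_way_routing_example(self):
        split = make_task_splits(
            old_assoc=[("m1", "d1")],
            new_assoc=[("m1", "d1x"), ("m1", "d2"), ("m2", "d1"),
                       ("m2", "d2"), ("m1b", "d3")],
            old_mirnas=["m1", "m1b", "m1c"],
            old_diseases=["d1", "d1x", "d1y"],
            seed=0,
        )
        pos = {t: [(m, d) for m, d, lab in split.tasks[t] if lab == 1]
               for t in split.tasks}
        assert pos["tp"] == [("m1", "d1x")]
        assert pos["td"] == [("m1", "d2"), ("m1b", "d3")]
        assert pos["tm"] == [("m2", "d1")]
        assert pos["tn"] == [("m2", "d2")]

    def test_routing_is_a_partition(self):
        rng = np.random.default_rng(0)
        old_m = [f"m{i}" for i in range(10)]
        old_d = [f"d{j}" for j in range(8)]
        new_m = ["mA", "mB"]
        new_d = ["dA"]
        all_m, all_d = old_m + new_m, old_d + new_d
        new_assoc = {(all_m[rng.integers(len(all_m))], all_d[rng.integers(len(all_d))])
                     for _ in range(25)}
        old_assoc = [("m0", "d0"), ("m1", "d2")]
        new_assoc -= set(old_assoc)
        split = make_task_splits(old_assoc, sorted(new_assoc), old_m, old_d, seed=1)
        routed = [
            (m, d) for t in split.tasks for m, d, lab in split.tasks[t] if lab == 1
        ]
        assert sorted(routed) == sorted(new_assoc)  # each lands exactly once

    def test_negatives_regime_matched_and_disjoint(self):
        old_m = [f"m{i}" for i in range(6)]
        old_d = [f"d{j}" for j in range(6)]
        new_assoc = [("m0", "dN"), ("mN", "d0"), ("m1", "d1")]
        split = make_task_splits([("m0", "d0")], new_assoc, old_m, old_d, seed=3)
        positives = {("m0", "d0"), *new_assoc}
        for t, pairs in split.tasks.items():
            negs = [(m, d) for m, d, lab in pairs if lab == 0]
            n_pos = sum(1 for _, _, lab in pairs if lab == 1)
            assert len(negs) == n_pos
            assert not set(negs) & positives
            for m, d in negs:
                if t == "tp":
                    assert m in old_m and d in old_d
                elif t == "td":
                    assert m in old_m and d == "dN"
                elif t == "tm":
                    assert m == "mN" and d in old_d
                else:
                    assert m == "mN" and d == "dN"

    def test_no_new_entities_empties_three_tasks(self):
        split = make_task_splits(
            [("m1", "d1")], [("m1", "d2"), ("m2", "d1")],
            ["m1", "m2", "m3"], ["d1", "d2", "d3"], seed=0,
        )
        assert split.tasks["td"] == [] and split.tasks["tm"] == []
        assert split.tasks["tn"] == []

    def test_unregistered_old_entity_rejected(self):
        with pytest.raises(InputError):
            make_task_splits([("mX", "d1")], [], ["m1"], ["d1"], seed=0)


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert all(v == 1.0 for v in m.values())

    def test_printed_four_point_example(self):
        scores = [0.9, 0.8, 0.3, 0.1]
        labels = [1, 0, 1, 0]
        m = compute_metrics(scores, labels)
        assert m["auc"] == pytest.approx(0.75)
        for k in ("accuracy", "precision", "recall", "f1"):
            assert m[k] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        want = conc / (len(pos) * len(neg))
        assert auc_score(scores, labels) == pytest.approx(want, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.random(20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        base = compute_metrics(scores, labels)
        perm = rng.permutation(20)
        assert compute_metrics(scores[perm], labels[perm]) == base

    def test_single_class_auc_rejected(self):
        with pytest.raises(InputError):
            auc_score([0.1, 0.9], [1, 1])

    def test_f1_is_harmonic_mean(self):
        m = compute_metrics([0.9, 0.9, 0.1, 0.9], [1, 1, 1, 0])
        p, r = m["precision"], m["recall"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))


class TestRepeatsAndPairedTest:
    def test_single_repeat_mean_and_zero_sd(self):
        report = repeat_experiment(lambda s: {"auc": 0.7 + s * 0}, n_repeats=1,
                                   base_seed=5)
        assert report.mean["auc"] == 0.7
        assert report.sd["auc"] == 0.0

    def test_seeds_are_consecutive_and_mean_consistent(self):
        report = repeat_experiment(lambda s: {"auc": float(s)}, n_repeats=4,
                                   base_seed=10)
        assert report.per_run["seed"].tolist() == [10, 11, 12, 13]
        assert report.mean["auc"] == pytest.approx(np.mean([10, 11, 12, 13]))

    def test_paired_ttest_matches_reference(self):
        rng = np.random.default_rng(2)
        a = rng.random(10)
        b = a + rng.normal(0.05, 0.02, size=10)
        t, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_vectors_give_p_one(self):
        assert paired_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == (0.0, 1.0)


@pytest.fixture(scope="module")
def tiny_run():
    cfg = RunConfig(n_mirna=50, n_disease=40, epochs=25)
    dataset = load_dataset(cfg, seed=11)
    return cfg, dataset


class TestEndToEnd:
    def test_tp_run_beats_chance_clearly(self, tiny_run):
        cfg, dataset = tiny_run
        metrics = run_task(dataset, "tp", cfg.experiment_config(), seed=11)
        assert metrics["auc"] > 0.7

    def test_all_four_tasks_run(self, tiny_run):
        cfg, dataset = tiny_run
        ec = cfg.experiment_config()
        ec.gcn = GCNConfig(hidden=(16, 8), epochs=8)
        for task in ("tp", "td", "tm", "tn"):
            m = run_task(dataset, task, ec, seed=11)
            assert set(m) == {"accuracy", "precision", "recall", "f1", "auc"}
            assert all(0.0 <= v <= 1.0 for v in m.values())

    def test_hetero_method_rejected_for_node_experiments(self, tiny_run):
        cfg, dataset = tiny_run
        ec = cfg.experiment_config()
        ec.graph_method = "hetero"
        with pytest.raises(InputError):
            run_task(dataset, "tp", ec, seed=11)


@pytest.fixture(scope="module")
def ranking_context():
    """Case-study setting: all candidate miRNAs for one disease, label-masked.

    Strongly recoverable generator settings so the planted links should
    dominate the top ranks.
    """
    from mdgcn.evaluation import (
        _build_graph,
        _sample_regime_negatives,
        _training_association_matrix,
    )
    from mdgcn.gcn import train
    from mdgcn.pair_graph import build_mdp_nodes
    from mdgcn.similarity import integrate_with_profile_kernel
    from mdgcn.synthetic import SyntheticSpec, generate

    d = generate(SyntheticSpec(n_mirna=150, n_disease=40, p_in=0.95, p_out=0.01,
                               similarity_signal=0.9, noise_sd=0.02,
                               holdout_fraction_old=0.5, seed=21))
    split = make_task_splits(d.old_pairs, d.new_pairs, d.old_mirnas,
                             d.old_diseases, d.new_mirnas, d.new_diseases,
                             seed=21)
    truth = set(d.assoc.positive_pairs())
    train_pos = set(split.train_pairs)
    # held-out links per old disease; rank for the best-covered one
    held = {}
    for m, dd in truth - train_pos:
        if dd in split.old_diseases and m in split.old_mirnas:
            held[dd] = held.get(dd, 0) + 1
    disease = max(held, key=held.get)

    train_assoc = _training_association_matrix(split)
    imsm = integrate_with_profile_kernel(d.mirna_sim, train_assoc, "mirna")
    idsm = integrate_with_profile_kernel(d.disease_sim, train_assoc, "disease")
    rng = np.random.default_rng(21)
    negs = _sample_regime_negatives(split.old_mirnas, split.old_diseases,
                                    len(train_pos), truth, rng)
    pairs = [(m, dd, 1, "train") for m, dd in split.train_pairs]
    pairs += [(m, dd, 0, "train") for m, dd in negs]
    neg_set = set(negs)
    candidates = [m for m in split.old_mirnas
                  if (m, disease) not in train_pos and (m, disease) not in neg_set]
    pairs += [(m, disease, 0, "test-masked") for m in candidates]
    if len(pairs) % 2:  # k=5 regular graph needs an even node count
        pairs.remove((negs[-1][0], negs[-1][1], 0, "train"))
    nodes = build_mdp_nodes(pairs, imsm, idsm)
    ec = ExperimentConfig(gcn=GCNConfig(hidden=(32, 16), epochs=40))
    graph = _build_graph(nodes, ec, 21)
    model = train(ec.gcn, graph, nodes, seed=21)
    return {"model": model, "graph": graph, "nodes": nodes, "truth": truth,
            "disease": disease, "train_pos": train_pos, "candidates": candidates}


class TestRanking:
    def test_training_positives_excluded_and_sorted(self, ranking_context):
        ctx = ranking_context
        ranked = rank_candidates(ctx["model"], ctx["graph"], ctx["nodes"],
                                 ctx["disease"])
        assert all((m, ctx["disease"]) not in ctx["train_pos"] for m, _ in ranked)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_top_k_larger_than_candidates_returns_all(self, ranking_context):
        ctx = ranking_context
        full = rank_candidates(ctx["model"], ctx["graph"], ctx["nodes"],
                               ctx["disease"], top_k=10_000)
        again = rank_candidates(ctx["model"], ctx["graph"], ctx["nodes"],
                                ctx["disease"], top_k=len(full))
        assert full == again

    def test_unknown_disease_rejected(self, ranking_context):
        ctx = ranking_context
        with pytest.raises(InputError):
            rank_candidates(ctx["model"], ctx["graph"], ctx["nodes"],
                            "no-such-disease")

    def test_planted_links_dominate_top_ranks(self, ranking_context):
        """Most top-10 candidates for the best-covered disease are true links."""
        ctx = ranking_context
        ranked = rank_candidates(ctx["model"], ctx["graph"], ctx["nodes"],
                                 ctx["disease"], top_k=10)
        hits = sum((m, ctx["disease"]) in ctx["truth"] for m, _ in ranked)
        assert hits >= 8
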