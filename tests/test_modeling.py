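import itertools

import numpy as np
import pytest

from trimint import (
    RunConfig,
    TrimintError,
    compute_metrics,
    cumulative_union,
    evaluate_cumulative,
    rank_auc,
)

from conftest import make_labels, make_matrix, make_scored


def brute_force_metrics(y_true, y_pred):
    """Confusion-matrix tabulation by explicit iteration."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def pairwise_auc(y_true, scores):
    """Probability a positive outranks a negative; ties count one half."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    if not pos or not neg:
        return float("nan")
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCumulativeUnion:
    def test_union_preserves_first_appearance_order(self):
        scored = [
            make_scored(("m1", "c1"), ["a", "b"], 0.9, 1),
            make_scored(("m2", "c2"), ["b", "c"], 0.8, 2),
        ]
        assert cumulative_union(scored, 2) == ["a", "b", "c"]

    def test_k_one_is_top_group(self):
        scored = [
            make_scored(("m1", "c1"), ["a", "b"], 0.9, 1),
            make_scored(("m2", "c2"), ["c"], 0.8, 2),
        ]
        assert cumulative_union(scored, 1) == ["a", "b"]

    def test_k_three_merges_three_best(self):
        scored = [
            make_scored(("m3", "c3"), ["e"], 0.7, 3),
            make_scored(("m1", "c1"), ["a"], 0.9, 1),
            make_scored(("m2", "c2"), ["b"], 0.8, 2),
            make_scored(("m4", "c4"), ["z"], 0.6, 4),
        ]
        assert cumulative_union(scored, 3) == ["a", "b", "e"]

    def test_out_of_range_k_rejected(self):
        scored = [make_scored(("m", "c"), ["a"], 0.9, 1)]
        with pytest.raises(TrimintError):
            cumulative_union(scored, 2)
        with pytest.raises(TrimintError):
            cumulative_union(scored, 0)


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        # TP=3, TN=4, FP=1, FN=2
        y_true = [1] * 5 + [0] * 5
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        acc, sens, spec, _ = compute_metrics(y_true, y_pred, np.zeros(10))
        assert (acc, sens, spec) == (0.7, 0.6, 0.8)

    def test_matches_brute_force_on_enumerated_grid(self):
        for tp, tn, fp, fn in itertools.product(range(7), repeat=4):
            if tp + fn == 0 or tn + fp == 0 or tp + tn + fp + fn == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            acc, sens, spec, _ = compute_metrics(y_true, y_pred, np.zeros(len(y_true)))
            b_acc, b_sens, b_spec = brute_force_metrics(y_true, y_pred)
            assert acc == pytest.approx(b_acc)
            assert sens == pytest.approx(b_sens)
            assert spec == pytest.approx(b_spec)

    def test_perfect_separation_auc_one(self):
        y = [0, 0, 1, 1]
        assert rank_auc(np.array(y), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_tied_scores_auc_half(self):
        assert rank_auc(np.array([0, 1, 0, 1]), np.ones(4)) == 0.5

    def test_auc_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            y = rng.integers(0, 2, size=12)
            if len(set(y)) < 2:
                continue
            scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=12)
            assert rank_auc(y, scores) == pytest.approx(pairwise_auc(y, scores))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        y = np.array([0, 1] * 8)
        s = rng.normal(size=16)
        base = rank_auc(y, s)
        assert rank_auc(y, np.exp(s)) == pytest.approx(base)
        assert rank_auc(y, 3 * s - 7) == pytest.approx(base)

    def test_single_class_truth_auc_nan_others_defined(self):
        acc, sens, spec, auc = compute_metrics([1, 1], [1, 0], np.array([0.9, 0.1]))
        assert np.isnan(auc) and np.isnan(spec)
        assert acc == 0.5 and sens == 0.5


class TestEvaluateCumulative:
    def _setup(self, n_groups, n_per_class=15, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_class
        genes, ids = [], []
        for g in range(n_groups):
            sig = np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)])
            genes.append(sig + 0.05 * rng.normal(size=n))
            ids.append(f"g{g}")
        C = make_matrix(np.vstack(genes), feature_ids=ids, role="mRNA")
        labs = make_labels(n_per_class, n_per_class)
        train = [s for i, s in enumerate(C.sample_ids) if i % 5 != 0]
        test = [s for i, s in enumerate(C.sample_ids) if i % 5 == 0]
        scored = [
            make_scored((f"m{g}", f"c{g}"), [f"g{g}"], 0.9 - 0.1 * g, g + 1)
            for g in range(n_groups)
        ]
        return scored, C.subset_samples(train), C.subset_samples(test), labs

    def test_rows_truncate_to_available_groups(self):
        scored, C_tr, C_te, labs = self._setup(3)
        cfg = RunConfig(top_k_groups=10, rf_trees=25)
        rows = evaluate_cumulative(scored, C_tr, C_te, labs, cfg, seed=1)
        assert [r.cumulative_rank for r in rows] == [1, 2, 3]

    def test_separable_fixture_saturates(self):
        scored, C_tr, C_te, labs = self._setup(2)
        rows = evaluate_cumulative(scored, C_tr, C_te, labs, RunConfig(rf_trees=25), seed=2)
        assert rows[0].accuracy >= 0.95
        assert rows[0].auc >= 0.95

    def test_gene_count_equals_union_size_and_is_nondecreasing(self):
        scored, C_tr, C_te, labs = self._setup(4)
        rows = evaluate_cumulative(scored, C_tr, C_te, labs, RunConfig(rf_trees=25), seed=3)
        for k, row in enumerate(rows, start=1):
            assert row.unique_gene_count == len(cumulative_union(scored, k))
        counts = [r.unique_gene_count for r in rows]
        assert counts == sorted(counts)

    def test_overlapping_train_test_rejected(self):
        scored, C_tr, _, labs = self._setup(1)
        with pytest.raises(TrimintError, match="disjoint"):
            evaluate_cumulative(scored, C_tr, C_tr, labs, RunConfig(), seed=0)
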