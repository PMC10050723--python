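import numpy as np
import pytest
from scipy import stats

from trimint import (
    TrimintError,
    filter_exclusion,
    filter_iqr,
    filter_missing,
    preprocess_cpg,
    ttest_filter,
)

from conftest import make_labels, make_matrix


def brute_force_iqr(values):
    """Sorted-order linear-interpolation quantiles, written independently."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    return quantile(0.75) - quantile(0.25)


def manual_welch(a, b):
    """Welch t statistic and two-sided p from the textbook formulas."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestFilterMissing:
    def test_strictly_more_than_threshold_removed(self):
        vals = np.ones((2, 10))
        vals[0, :3] = np.nan  # 30% missing -> removed at 0.2
        vals[1, :2] = np.nan  # 20% missing -> kept (threshold is strict "more than")
        m = make_matrix(vals, role="CpG")
        out, rep = filter_missing(m, 0.2)
        assert out.feature_ids == ["f1"]
        assert rep.removed_ids == ["f0"]

    def test_survivors_mean_imputed(self):
        vals = np.array([[np.nan, np.nan, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]])
        m = make_matrix(vals, role="CpG")
        out, _ = filter_missing(m, 0.2)
        np.testing.assert_allclose(out.values()[0, :2], [4.5, 4.5])
        np.testing.assert_allclose(out.values()[0, 2:], vals[0, 2:])

    def test_all_missing_feature_always_removed(self):
        m = make_matrix(np.full((1, 5), np.nan), role="CpG")
        out, rep = filter_missing(m, 0.99)
        assert out.n_features == 0 and rep.removed_ids == ["f0"]

    def test_identity_when_complete(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(4, 6)), role="CpG")
        out, rep = filter_missing(m, 0.2)
        np.testing.assert_array_equal(out.values(), m.values())
        assert rep.removed_ids == []


class TestFilterIqr:
    def test_constant_feature_removed(self):
        m = make_matrix(np.vstack([np.zeros(8), np.linspace(0, 1, 8)]), role="CpG")
        out, _ = filter_iqr(m, 0.1)
        assert out.feature_ids == ["f1"]

    def test_matches_brute_force_quantile_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.beta(0.5, 0.5, size=(50, 21))
        m = make_matrix(vals, role="CpG")
        out, _ = filter_iqr(m, 0.1)
        expected = [f"f{i}" for i in range(50) if brute_force_iqr(vals[i]) > 0.1]
        assert out.feature_ids == expected

    def test_boundary_is_strict(self):
        # IQR of {0, 0.05, 0.5, 1.0}: q25 = 0.0875, q75 = 0.625 -> 0.5375 > 0.1 kept
        m = make_matrix([[0.0, 0.05, 0.5, 1.0]], role="CpG")
        out, _ = filter_iqr(m, 0.1)
        assert out.n_features == 1
        assert filter_iqr(m, brute_force_iqr([0.0, 0.05, 0.5, 1.0]))[0].n_features == 0

    def test_negative_threshold_is_identity(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(5, 7)), role="CpG")
        out, _ = filter_iqr(m, -1.0)
        assert out.feature_ids == m.feature_ids

    def test_missing_values_rejected(self):
        m = make_matrix([[np.nan, 1.0, 2.0]], role="CpG")
        with pytest.raises(TrimintError, match="missing"):
            filter_iqr(m)


class TestFilterExclusion:
    def test_blocklisted_removed_unknown_counted(self):
        m = make_matrix(np.ones((3, 4)), feature_ids=["f1", "f2", "f3"])
        out, rep = filter_exclusion(m, [{"f2"}, {"zz"}])
        assert out.feature_ids == ["f1", "f3"]
        assert rep.removed_ids == ["f2"]
        assert "unknown_blocklist_ids=1" in rep.notes

    def test_empty_blocklist_identity(self):
        m = make_matrix(np.ones((2, 4)))
        out, rep = filter_exclusion(m, [])
        assert out.feature_ids == m.feature_ids and rep.removed_ids == []


class TestTtestFilter:
    def test_separated_feature_retained_null_removed(self):
        rng = np.random.default_rng(0)
        strong = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])
        flat = np.tile(np.arange(20.0) % 3, 1)
        m = make_matrix(np.vstack([strong, flat]))
        labs = make_labels(10, 10)
        out, _ = ttest_filter(m, labs, 0.05)
        assert out.feature_ids == ["f0"]

    def test_matches_manual_welch_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 30))
        vals[:10, 15:] += rng.uniform(0.5, 1.5, size=(10, 1))
        m = make_matrix(vals)
        labs = make_labels(15, 15)
        out, _ = ttest_filter(m, labs, 0.05)
        expected = [
            f"f{i}"
            for i in range(40)
            if manual_welch(vals[i, 15:], vals[i, :15])[1] < 0.05
        ]
        assert out.feature_ids == expected

    def test_constant_identical_feature_removed(self):
        m = make_matrix(np.ones((1, 10)))
        out, _ = ttest_filter(m, make_labels(5, 5), 0.05)
        assert out.n_features == 0

    def test_pooled_variant_matches_scipy(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(20, 24))
        m = make_matrix(vals)
        labs = make_labels(12, 12)
        out, _ = ttest_filter(m, labs, 0.3, welch=False)
        expected = [
            f"f{i}"
            for i in range(20)
            if stats.ttest_ind(vals[i, 12:], vals[i, :12], equal_var=True).pvalue < 0.3
        ]
        assert out.feature_ids == expected

    def test_disable_keeps_all_nondegenerate(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(10, 12)))
        out, _ = ttest_filter(m, make_labels(6, 6), 1.0)
        assert out.feature_ids == m.feature_ids


class TestFilterProperties:
    @pytest.mark.parametrize("which", ["missing", "iqr", "ttest"])
    def test_idempotent(self, which):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(30, 16))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = make_matrix(vals, role="CpG")
        labs = make_labels(8, 8)
        if which == "missing":
            f = lambda x: filter_missing(x, 0.15)[0]
        elif which == "iqr":
            m, _ = filter_missing(m, 0.99)
            f = lambda x: filter_iqr(x, 0.5)[0]
        else:
            m, _ = filter_missing(m, 0.99)
            f = lambda x: ttest_filter(x, labs, 0.2)[0]
        once = f(m)
        twice = f(once)
        assert twice.feature_ids == once.feature_ids
        np.testing.assert_array_equal(twice.values(), once.values())

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(size=(20, 14)), role="CpG")
        perm = list(rng.permutation(m.sample_ids))
        out_a, _ = filter_iqr(m, 0.5)
        out_b, _ = filter_iqr(m.subset_samples(perm), 0.5)
        assert out_a.feature_ids == out_b.feature_ids

    def test_report_counts_reconcile(self):
        rng = np.random.default_rng(12)
        vals = rng.beta(2, 2, size=(25, 10))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = make_matrix(vals, role="CpG")
        out, reports = preprocess_cpg(m, 0.2, 0.05, [{"f0", "f1"}])
        for rep in reports:
            assert rep.features_out == rep.features_in - len(rep.removed_ids)
        assert reports[0].features_in == 25
        assert reports[-1].features_out == out.n_features
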