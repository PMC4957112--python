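"""Evaluation statistics against hand calculations and independent oracles."""

import numpy as np
import pytest
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from oracles import brute_auc, exact_wilcoxon_p, hanley_mcneil_ci
from rbforest.metrics import (
    auc_ci,
    class_error,
    kfold_cv,
    optimal_threshold,
    rmse,
    roc_auc,
    roc_report,
    wilcoxon_paired,
)


class TestPointMetrics:
    def test_rmse_hand_value(self):
        # errors (1, 0, -1): sqrt((1 + 0 + 1) / 3)
        assert rmse([1.0, 2.0, 3.0], [0.0, 2.0, 4.0]) == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_rmse_zero_on_equal(self, rng):
        y = rng.normal(size=20)
        assert rmse(y, y) == 0.0

    def test_class_error_hand_value(self):
        assert class_error([0, 1, 1, 0], [0, 1, 0, 0]) == 0.25

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            class_error([], [])


class TestRocAuc:
    def test_perfect_and_reversed(self):
        y = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y) == 0.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            # coarse grid forces plenty of ties
            scores = rng.integers(0, 5, n) / 4.0
            assert roc_auc(scores, labels) == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.normal(size=200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            roc_auc([0.1, 0.9], [1, 2])
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestAucCI:
    def test_formula_oracle(self):
        lo, hi = auc_ci(0.7, 431, 702)
        olo, ohi = hanley_mcneil_ci(0.7, 431, 702)
        assert lo == pytest.approx(olo, abs=1e-10)
        assert hi == pytest.approx(ohi, abs=1e-10)

    def test_degenerate_auc_one(self):
        assert auc_ci(1.0, 50, 50) == (1.0, 1.0)

    def test_interval_contains_point_and_is_clipped(self):
        lo, hi = auc_ci(0.95, 10, 10)
        assert 0.0 <= lo <= 0.95 <= hi <= 1.0

    def test_width_shrinks_with_sample_size(self):
        w_small = np.diff(auc_ci(0.7, 20, 20))[0]
        w_large = np.diff(auc_ci(0.7, 2000, 2000))[0]
        assert w_large < w_small / 5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc_ci(1.2, 10, 10)
        with pytest.raises(ValueError):
            auc_ci(0.5, 0, 10)


class TestOptimalThreshold:
    @staticmethod
    def brute(scores, labels):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        best = None
        for cut in np.unique(scores):  # ascending -> first strict max = lowest cut
            called = scores >= cut
            sens = (called & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~called & (labels == 0)).sum() / (labels == 0).sum()
            if best is None or sens + spec - 1 > best[1] + 1e-15:
                best = (cut, sens + spec - 1, sens, spec)
        return best

    def test_separable_hand_case(self):
        thr, sens, spec, acc = optimal_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == 0.8 and sens == 1.0 and spec == 1.0 and acc == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 6, n) / 5.0
            thr, sens, spec, _ = optimal_threshold(scores, labels)
            bthr, bj, bsens, bspec = self.brute(scores, labels)
            assert thr == bthr
            assert sens + spec - 1 == pytest.approx(bj, abs=1e-12)

    def test_roc_report_consistency(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100) + labels
        rep = roc_report(scores, labels)
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert rep.auc == roc_auc(scores, labels)
        assert len(rep.curve) >= 2  # includes the (0,0) and (1,1) endpoints


class TestKFold:
    def test_folds_partition_and_stratify(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0.2).astype(int)
        res = kfold_cv(X, y, LogisticRegression(), k=10, seed=3)
        counts = np.bincount(res.fold_assignments, minlength=10)
        assert counts.sum() == 100 and counts.min() >= 9
        for f in range(10):
            fold_y = y[res.fold_assignments == f]
            assert 0 < fold_y.sum() < len(fold_y)  # both classes in every fold
        assert len(res.fold_metrics) == 10
        assert set(res.mean_metrics) == set(res.fold_metrics[0])
        assert res.mean_metrics["auc"] > 0.9

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        r1 = kfold_cv(X, y, LogisticRegression(), k=5, seed=7)
        r2 = kfold_cv(X, y, LogisticRegression(), k=5, seed=7)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.mean_metrics == r2.mean_metrics

    def test_regression_reports_rmse(self, rng):
        from sklearn.linear_model import LinearRegression

        X = rng.normal(size=(50, 2))
        y = X @ [1.0, -2.0] + 0.01 * rng.normal(size=50)
        res = kfold_cv(X, y, LinearRegression(), k=5, seed=0)
        assert set(res.mean_metrics) == {"rmse"}
        assert res.mean_metrics["rmse"] < 0.05

    def test_k_exceeding_n_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="k cannot exceed"):
            kfold_cv(X, np.array([0, 1, 0, 1, 0]), LogisticRegression(), k=6)


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        w, p = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (w, p) == (0.0, 1.0)

    def test_one_sided_antisymmetry(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        _, p_less = wilcoxon_paired(x, y, "less")
        _, p_greater = wilcoxon_paired(y, x, "greater")
        assert p_less == pytest.approx(p_greater, abs=1e-12)

    def test_matches_scipy_with_ties_and_zeros(self, rng):
        for alt, scipy_alt in (("two_sided", "two-sided"), ("less", "less"), ("greater", "greater")):
            # coarse grid -> zeros (dropped) and tied |d| (midranked)
            x = rng.integers(0, 6, 25) / 2.0
            y = rng.integers(0, 6, 25) / 2.0
            if (x == y).all():
                continue
            w, p = wilcoxon_paired(x, y, alt)
            ref = scipy.stats.wilcoxon(
                x, y, zero_method="wilcox", correction=True, alternative=scipy_alt,
                method="approx",
            )
            assert w == ref.statistic if alt != "two_sided" else True
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_exact_enumeration(self, rng):
        # no zeros, no tied |d|: the normal approximation with continuity
        # correction should sit close to the exact distribution
        d = rng.normal(size=12)
        d = d[np.abs(d) > 0.05] + np.linspace(0, 1e-6, len(d[np.abs(d) > 0.05]))
        x = d
        y = np.zeros_like(d)
        _, p = wilcoxon_paired(x, y, "less")
        p_exact = exact_wilcoxon_p(d, "less")
        assert p == pytest.approx(p_exact, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="alternative"):
            wilcoxon_paired([1.0], [2.0], "sideways")
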