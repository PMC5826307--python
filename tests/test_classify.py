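"""Classification: MANOVA gate, LOOCV-SVM, subset search, kappa, R2/RMSE."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crownarch import (
    SVMConfig,
    cohens_kappa,
    loocv_svm,
    manova_gate,
    r2_rmse,
    subset_search,
)
from crownarch.classify import _wilks_p


def make_table(rng, n_per_class=10, n_features=3, separation=10.0, classes=4):
    rows = []
    for c in range(classes):
        mu = separation * c
        for i in range(n_per_class):
            feats = rng.normal(mu, 1.0, n_features)
            rows.append({"tree_id": f"c{c}t{i}", "species": f"S{c}",
                         **{f"f{j}": feats[j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestManova:
    def test_gross_separation_tiny_p(self, rng):
        table = make_table(rng, separation=10.0)
        p = manova_gate(table, ["f0", "f1", "f2"])
        assert p < 1e-6

    def test_identical_distributions_warn_and_large_p(self, rng):
        table = make_table(rng, separation=0.0, classes=2, n_per_class=20)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            p = manova_gate(table, ["f0", "f1", "f2"])
        assert 0 < p <= 1

    def test_constant_column_triggers_ridge_retry(self, rng):
        table = make_table(rng, separation=5.0)
        table["f0"] = 1.0
        with pytest.warns(UserWarning, match="ridge"):
            p = manova_gate(table, ["f0", "f1", "f2"])
        assert np.isfinite(p) and p < 1e-6

    def test_null_calibration_uniform_p(self):
        """Under the null (identical class distributions) the Wilks p-value
        is uniform: K-S test over 200 replicates."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            X = rng.normal(0, 1, (40, 3))
            groups = np.repeat(["a", "b"], 20)
            pvals.append(_wilks_p(X, groups))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_matches_statsmodels_wilks(self, rng):
        """Dual route: our Rao-F Wilks p-value equals statsmodels MANOVA."""
        from statsmodels.multivariate.manova import MANOVA

        table = make_table(rng, separation=1.0)
        X = table[["f0", "f1", "f2"]].to_numpy()
        y = table["species"].to_numpy()
        ours = _wilks_p(X, y)
        mv = MANOVA(endog=X, exog=pd.get_dummies(y, drop_first=False).to_numpy().astype(float))
        res = mv.mv_test(hypotheses=[("species", np.eye(4)[1:] - np.eye(4)[:-1][:, :4])])
        # easier: use the formula interface
        df = table.rename(columns={"species": "g"})
        mv = MANOVA.from_formula("f0 + f1 + f2 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        sm_p = float(tab.loc["Wilks' lambda", "Pr > F"])
        assert ours == pytest.approx(sm_p, abs=1e-8)

    def test_preconditions(self, rng):
        table = make_table(rng, n_per_class=2, n_features=3)
        with pytest.raises(ValueError, match="n >"):
            manova_gate(table, ["f0", "f1", "f2", "f0"][:4])


class TestLoocv:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        table = make_table(rng, separation=10.0)
        rep = loocv_svm(table, ["f0", "f1", "f2"])
        assert rep.overall_accuracy == 1.0
        assert rep.kappa == 1.0
        assert all(v == 1.0 for v in rep.recall.values())
        assert all(v == 1.0 for v in rep.precision.values())

    def test_row_order_invariance(self, rng):
        table = make_table(rng, separation=1.0)
        rep1 = loocv_svm(table, ["f0", "f1", "f2"])
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rep2 = loocv_svm(shuffled, ["f0", "f1", "f2"])
        assert rep1.overall_accuracy == rep2.overall_accuracy
        pd.testing.assert_frame_equal(rep1.confusion, rep2.confusion)
        pd.testing.assert_series_equal(rep1.predictions, rep2.predictions)

    def test_overlapping_gaussians_near_bayes_accuracy(self):
        """1-D two-class LOOCV accuracy within 0.05 of the Bayes-rule
        accuracy Phi(0.5) for N(0,1) vs N(1,1)."""
        rng = np.random.default_rng(9)
        n = 100
        rows = []
        for i in range(n // 2):
            rows.append({"tree_id": f"a{i}", "species": "A", "x": rng.normal(0, 1)})
            rows.append({"tree_id": f"b{i}", "species": "B", "x": rng.normal(1, 1)})
        table = pd.DataFrame(rows)
        rep = loocv_svm(table, ["x"])
        bayes = stats.norm.cdf(0.5)  # ~0.6915
        assert rep.overall_accuracy == pytest.approx(bayes, abs=0.05)

    def test_label_shuffle_gives_chance_accuracy(self):
        """Leakage detector: shuffled labels score near 1/#classes."""
        rng = np.random.default_rng(4)
        table = make_table(rng, n_per_class=15, separation=10.0)
        table["species"] = rng.permutation(table["species"].to_numpy())
        rep = loocv_svm(table, ["f0", "f1", "f2"])
        n = len(table)
        # 99.9% binomial bound around chance 0.25
        bound = 0.25 + 3.3 * math.sqrt(0.25 * 0.75 / n)
        assert rep.overall_accuracy <= bound

    def test_metrics_consistent_with_confusion(self, rng):
        table = make_table(rng, separation=0.8)
        rep = loocv_svm(table, ["f0", "f1", "f2"])
        m = rep.confusion.to_numpy()
        assert m.sum() == len(table)
        assert rep.overall_accuracy == pytest.approx(np.trace(m) / m.sum())
        assert rep.kappa == pytest.approx(cohens_kappa(m))
        for i, c in enumerate(rep.confusion.index):
            assert rep.recall[c] == pytest.approx(m[i, i] / m[i].sum())

    def test_singleton_class_error_names_class(self, rng):
        table = make_table(rng).iloc[:-9]  # S3 keeps a single tree
        with pytest.raises(ValueError, match="S3"):
            loocv_svm(table, ["f0"])


class TestSubsetSearch:
    def test_counts_equal_binomials_for_all_sizes(self, rng):
        table = make_table(rng, n_features=13 - 9)  # columns not all used
        pool = [f"p{i}" for i in range(13)]
        for c in pool:
            table[c] = rng.normal(size=len(table))
        res = subset_search(table, pool, range(1, 14), count_only=True)
        for k in range(1, 14):
            assert res.per_size[k].n_cases == math.comb(13, k)

    def test_three_column_pool_enumeration(self, rng):
        table = make_table(rng, separation=5.0)
        res = subset_search(table, ["f0", "f1", "f2"], sizes=[1, 2, 3])
        assert sum(sr.n_cases for sr in res.per_size.values()) == 7
        assert res.best_accuracy == 1.0
        # tie-break: smallest subset, lexicographic
        assert res.best_subset == ("f0",)
        assert res.best_report is not None
        assert res.best_report.overall_accuracy == res.best_accuracy

    def test_size_out_of_range_raises(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError, match="size"):
            subset_search(table, ["f0", "f1"], sizes=[3])

    def test_injected_evaluator_is_used(self, rng):
        table = make_table(rng)
        calls = []
        res = subset_search(
            table, ["f0", "f1", "f2"], sizes=[2],
            evaluator=lambda t, cols: calls.append(cols) or 0.5,
        )
        assert len(calls) == 3
        assert res.per_size[2].best_accuracy == 0.5


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.diag([10, 10, 10, 10])) == 1.0

    def test_chance_agreement(self):
        assert cohens_kappa([[5, 5], [5, 5]]) == 0.0

    def test_hand_computed_value(self):
        # p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        assert cohens_kappa([[9, 1], [1, 9]]) == pytest.approx(0.8, abs=1e-12)

    def test_diagonal_matrix_is_one(self, rng):
        # any all-diagonal confusion (perfect agreement) scores 1
        assert cohens_kappa(np.diag(rng.integers(1, 20, 5))) == pytest.approx(1.0)

    def test_consistent_relabeling_is_not_agreement(self):
        # an off-diagonal permutation is total disagreement under Cohen's
        # formula, not a hidden perfect score
        assert cohens_kappa([[0, 7], [7, 0]]) == pytest.approx(-1.0)

    def test_rank_one_matrix_is_zero(self, rng):
        r = rng.integers(1, 10, 4)
        c = rng.integers(1, 10, 4)
        assert cohens_kappa(np.outer(r, c)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cell(self):
        m = np.zeros((3, 3)); m[1, 1] = 12
        assert cohens_kappa(m) == 1.0

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.ones((2, 3)))


class TestR2Rmse:
    def test_identity_vectors(self):
        r2, rmse = r2_rmse(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r2 == pytest.approx(1.0) and rmse == 0.0

    def test_hand_example(self):
        r2, rmse = r2_rmse(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert rmse == pytest.approx(math.sqrt(1 / 3), abs=1e-12)
        assert 0 < r2 <= 1

    def test_r2_is_squared_correlation(self, rng):
        d = rng.normal(0, 1, 50)
        ref = 2 * d + rng.normal(0, 0.5, 50)
        r2, _ = r2_rmse(d, ref)
        assert r2 == pytest.approx(np.corrcoef(d, ref)[0, 1] ** 2, abs=1e-10)

    def test_constant_estimates_sentinel(self):
        with pytest.warns(UserWarning, match="variance"):
            r2, rmse = r2_rmse(np.full(5, 2.0), np.arange(5.0))
        assert np.isnan(r2) and rmse > 0
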