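import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from almkit.stats import (
    classification_metrics, fit_logistic, games_howell,
    kruskal_wallis_eta2, roc_auc, run_validation, spearman_matrix,
)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        g = kruskal_wallis_eta2([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert g.H == pytest.approx(7.2)
        assert g.eta2 == pytest.approx((7.2 - 2) / 6)

    def test_identical_groups_give_zero_h(self):
        g = kruskal_wallis_eta2([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert g.H == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=12), rng.normal(1, 1, 10), rng.normal(2, 1, 8)]
        a = kruskal_wallis_eta2(groups)
        b = kruskal_wallis_eta2([np.exp(g) for g in groups])
        assert a.H == pytest.approx(b.H)
        assert a.p == pytest.approx(b.p)

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_eta2([[1, 2, 3], []])
        with pytest.raises(ValueError):
            kruskal_wallis_eta2([[1, 2, 3], [4]])


class TestGamesHowell:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        (res,) = games_howell([g, g])
        assert res.mean_diff == 0.0
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_reject_like_permutation_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(10, 1, 30)
        (res,) = games_howell([a, b])
        assert res.p < 0.001
        # permutation oracle on the mean difference agrees on rejection
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        for _ in range(500):
            rng.shuffle(pooled)
            count += abs(pooled[:30].mean() - pooled[30:].mean()) >= obs
        assert count / 500 < 0.001 + 1e-9

    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(2)
        res = games_howell([rng.normal(size=10) for _ in range(3)])
        assert len(res) == 3

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            games_howell([[1.0, 2.0], [3.0, 4.0, 5.0]])

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 20), rng.normal(0.8, 2, 25),
                  rng.normal(1.5, 1, 15)]
        ours = games_howell(groups, labels=["g0", "g1", "g2"])
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": ["g0"] * 20 + ["g1"] * 25 + ["g2"] * 15})
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        ref = ref.sort_values(["A", "B"]).reset_index(drop=True)
        for mine, (_, row) in zip(ours, ref.iterrows()):
            assert mine.df == pytest.approx(row["df"], rel=1e-6)
            assert mine.p == pytest.approx(row["pval"], abs=2e-3)


class TestSpearman:
    def test_perfect_monotone_association(self):
        m = spearman_matrix(pd.DataFrame({"x": [1, 2, 3], "y": [10, 20, 30],
                                          "z": [30, 20, 10]}))
        assert m.rho.loc["x", "y"] == pytest.approx(1.0)
        assert m.rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_ties_equal_midrank_pearson(self):
        x = np.array([1, 2, 2, 3, 4, 4, 4, 5.0])
        y = np.array([2, 1, 3, 3, 5, 4, 6, 6.0])
        m = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        oracle, _ = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))
        assert m.rho.loc["x", "y"] == pytest.approx(oracle)

    def test_pairwise_complete_and_sparse_cells(self):
        df = pd.DataFrame({
            "x": [1, 2, 3, 4, np.nan, np.nan],
            "y": [1, 2, 3, 4, 5, 6.0],
            "z": [np.nan, np.nan, np.nan, np.nan, 1, 2.0]})
        m = spearman_matrix(df)
        assert m.rho.loc["x", "y"] == pytest.approx(1.0)
        assert np.isnan(m.rho.loc["x", "z"])  # fewer than 3 complete pairs

    def test_invariant_under_monotone_transform_of_one_variable(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        a = spearman_matrix(df).rho.loc["x", "y"]
        df["x"] = np.exp(df["x"])
        b = spearman_matrix(df).rho.loc["x", "y"]
        assert a == pytest.approx(b)


def _irls_logistic(X, y, iters=200, tol=1e-12):
    """Independent iteratively-reweighted least-squares fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        z = eta + (y - p) / w
        new = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestLogistic:
    def test_coefficients_match_irls_oracle(self):
        rng = np.random.default_rng(5)
        n = 20
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        logit = -0.3 + 1.2 * x1 - 0.8 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        fit = fit_logistic(pd.Series(y),
                           covariates=pd.DataFrame({"x1": x1, "x2": x2}))
        X = np.column_stack([np.ones(n), x1, x2])
        oracle = _irls_logistic(X, y.astype(float))
        assert fit.params.to_numpy() == pytest.approx(oracle, abs=1e-6)

    def test_null_model_nagelkerke_is_zero(self):
        y = pd.Series([0, 1] * 15)
        fit = fit_logistic(y)
        assert fit.nagelkerke_r2 == 0.0
        assert fit.minus2_loglik == pytest.approx(-2 * 30 * np.log(0.5))

    def test_perfect_separation_flagged_not_raised(self):
        y = pd.Series([0] * 10 + [1] * 10)
        x = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        fit = fit_logistic(y, covariates=x)
        assert fit.separated

    def test_rank_deficient_design_rejected(self):
        y = pd.Series([0, 1] * 10)
        x = pd.DataFrame({"a": np.arange(20.0), "b": 2 * np.arange(20.0)})
        with pytest.raises(ValueError):
            fit_logistic(y, covariates=x)

    def test_ordinal_factor_uses_three_contrasts(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame({"alm": rng.integers(1, 5, 80)})
        y = pd.Series((rng.random(80) < 0.3 + 0.1 * scores["alm"]).astype(int))
        fit = fit_logistic(y, ordinal=scores)
        assert fit.wald["alm"].df == 3
        assert {"alm[2]", "alm[3]", "alm[4]"} <= set(fit.params.index)

    def test_nested_model_never_fits_worse(self, planted_cohort_table):
        df = planted_cohort_table.dropna(subset=["iq"])
        y = (df["group"] == "asd").astype(int)
        base = fit_logistic(y, covariates=df[["iq", "age"]])
        rng = np.random.default_rng(7)
        noisy = df[["iq", "age"]].copy()
        noisy["noise"] = rng.normal(size=len(df))
        bigger = fit_logistic(y, covariates=noisy)
        assert bigger.minus2_loglik <= base.minus2_loglik + 1e-8
        assert bigger.nagelkerke_r2 >= base.nagelkerke_r2 - 1e-8


class TestClassificationAndROC:
    def test_probabilities_equal_to_labels(self):
        acc, sens, spec = classification_metrics(
            np.array([0, 0, 1, 1.0]), np.array([0, 0, 1, 1]))
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_half_probabilities_tie_to_positive(self):
        acc, sens, spec = classification_metrics(
            np.full(10, 0.5), np.array([0, 1] * 5))
        assert sens == 1.0 and spec == 0.0

    def test_hand_built_confusion(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.6, 0.7])
        acc, sens, spec = classification_metrics(p, y)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(0.5)
        assert acc == pytest.approx(0.625)

    def test_auc_concordance_example(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_degenerate_aucs(self):
        assert roc_auc([0, 0, 1, 1.0], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([0.5] * 4, [0, 0, 1, 1]).auc == 0.5

    def test_auc_complement_sums_to_one(self):
        rng = np.random.default_rng(8)
        s = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        a = roc_auc(s, y).auc
        b = roc_auc(1 - s, y).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_curve_is_monotone(self):
        rng = np.random.default_rng(9)
        r = roc_auc(rng.random(50), (rng.random(50) < 0.4).astype(int))
        assert np.all(np.diff(r.tpr) >= 0)
        assert np.all(np.diff(r.fpr) >= 0)


class TestRunValidation:
    def test_all_models_share_the_same_subsample(self, planted_cohort_table):
        rep = run_validation(planted_cohort_table)
        ns = {fit.n_used for fit in rep.models.values()}
        assert ns == {rep.n_used}
        assert len(rep.excluded_ids) == 5  # the planted missing-IQ rows

    def test_report_has_nine_models_and_roc_curves(self, planted_cohort_table):
        rep = run_validation(planted_cohort_table)
        assert len(rep.models) == 9
        assert set(rep.roc) == set(rep.models)
        assert "baseline" in rep.models and "combined" in rep.models

    def test_group_comparisons_cover_every_alm(self, planted_cohort_table):
        rep = run_validation(planted_cohort_table)
        assert len(rep.group_comparisons) == 7
        # two groups: no post-hoc contrasts
        assert all(g.posthoc == () for g in rep.group_comparisons.values())

    def test_duplicate_ids_rejected(self, planted_cohort_table):
        bad = pd.concat([planted_cohort_table, planted_cohort_table.iloc[:1]])
        with pytest.raises(ValueError):
            run_validation(bad)
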