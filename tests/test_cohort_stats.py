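"""Group comparisons, odds ratios, stepwise regression and ROC/Youden."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ferriscope.cohort_stats import (
    ContingencyTable2x2,
    compare_groups,
    correlate,
    odds_ratio_2x2,
    roc_youden,
    stepwise_t2star_model,
)


class TestCompareGroups:
    def test_three_identical_groups_null_result(self):
        vals = [1.0, 2.0, 3.0] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_groups(vals, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_anova_matches_textbook_sum_of_squares(self):
        """Hand-worked one-way ANOVA: F = (SSB/2) / (SSW/6) = 3.0."""
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0], "g3": [3.0, 4.0, 5.0]}
        vals = sum(groups.values(), [])
        labels = sum(([g] * 3 for g in groups), [])
        grand = np.mean(vals)
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 6)
        assert f_oracle == pytest.approx(3.0)
        res = compare_groups(vals, labels)
        assert res.test == "anova"
        assert res.statistic == pytest.approx(f_oracle, rel=1e-12)

    def test_categorical_routes_to_chi2(self):
        vals = ["yes"] * 10 + ["no"] * 10
        labels = ["a"] * 10 + ["b"] * 10
        res = compare_groups(vals, labels, categorical=True)
        assert res.test == "chi2"
        assert res.p_value < 0.001

    def test_bonferroni_pairwise_at_least_unadjusted(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30),
                               rng.normal(2, 1, 30)])
        labels = np.repeat(["a", "b", "c"], 30)
        res = compare_groups(vals, labels)
        for (ga, gb), p_adj in res.pairwise_bonferroni.items():
            xa, xb = vals[labels == ga], vals[labels == gb]
            if res.test == "anova":
                p_raw = stats.ttest_ind(xa, xb).pvalue
            else:
                p_raw = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            assert p_adj >= p_raw - 1e-15
            assert p_adj <= 1.0

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCorrelate:
    def test_perfect_linear_is_pearson_one(self):
        x = np.arange(10.0)
        r, p, method = correlate(x, 2 * x + 1, force_method="pearson")
        assert r == pytest.approx(1.0)

    def test_rank_reversal_is_spearman_minus_one(self):
        x = np.arange(10.0)
        r, _, _ = correlate(x, np.exp(-x), force_method="spearman")
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _, _ = correlate(x, y, force_method="pearson")
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOddsRatio:
    def test_study_mio_table(self):
        """Deficient (23/107) vs insufficient (3/96) myocardial overload."""
        res = odds_ratio_2x2(ContingencyTable2x2(23, 84, 3, 93))
        assert res.or_value == pytest.approx((23 * 93) / (84 * 3), rel=1e-12)
        assert round(res.or_value, 2) == 8.49
        assert res.ci_low == pytest.approx(2.46, abs=0.01)
        assert res.ci_high == pytest.approx(29.29, abs=0.05)

    def test_symmetric_table_or_one(self):
        res = odds_ratio_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.or_value == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_matches_logistic_mle_oracle(self):
        """Woolf interval equals the single-predictor logistic Wald interval."""
        import statsmodels.api as sm

        t = ContingencyTable2x2(122, 81, 23, 52)
        res = odds_ratio_2x2(t)
        y = np.concatenate([np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)])
        x = np.concatenate([np.ones(t.a + t.b), np.zeros(t.c + t.d)])
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert res.or_value == pytest.approx(np.exp(fit.params[1]), rel=1e-6)
        assert res.log_se == pytest.approx(fit.bse[1], rel=1e-4)

    def test_transposed_exposure_is_reciprocal(self):
        t = ContingencyTable2x2(23, 84, 3, 93)
        swapped = ContingencyTable2x2(3, 93, 23, 84)
        a, b = odds_ratio_2x2(t), odds_ratio_2x2(swapped)
        assert a.or_value == pytest.approx(1.0 / b.or_value, rel=1e-12)
        width_a = np.log(a.ci_high) - np.log(a.ci_low)
        width_b = np.log(b.ci_high) - np.log(b.ci_low)
        assert width_a == pytest.approx(width_b, rel=1e-12)

    def test_zero_cell_errors_without_correction(self):
        with pytest.raises(ValueError, match="undefined OR"):
            odds_ratio_2x2(ContingencyTable2x2(5, 0, 3, 7))
        res = odds_ratio_2x2(ContingencyTable2x2(5, 0, 3, 7),
                             continuity_correction=0.5)
        assert np.isfinite(res.or_value)


class TestStepwise:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        df = pd.DataFrame({"y": y, "x": y})
        rep = stepwise_t2star_model(df, "y", ["x"])
        assert rep.retained == ("x",)
        assert rep.multivariate.loc["x", "beta"] == pytest.approx(1.0)
        assert rep.multivariate.loc["x", "vif"] == pytest.approx(1.0)
        assert rep.univariate.loc["x", "p_value"] < 1e-10

    def test_redundant_predictor_is_not_retained(self):
        """x2 = x1 + tiny noise adds nothing once x1 is in the model."""
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=300)
        x2 = x1 + rng.normal(scale=0.05, size=300)
        y = 2 * x1 + rng.normal(size=300)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        rep = stepwise_t2star_model(df, "y", ["x1", "x2"])
        assert rep.retained == ("x1",)

    def test_singular_design_errors(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        df = pd.DataFrame({"y": rng.normal(size=200), "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            stepwise_t2star_model(df, "y", ["a", "b"])

    def test_sample_size_guard(self):
        df = pd.DataFrame(np.random.default_rng(3).normal(size=(30, 4)),
                          columns=["y", "a", "b", "c"])
        with pytest.raises(ValueError, match="need n"):
            stepwise_t2star_model(df, "y", ["a", "b", "c"])

    def test_retained_survive_removal_threshold(self):
        """Every retained variable stays significant given the others."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = rng.normal(size=(278, 5))
        y = 0.4 * X[:, 0] + 0.3 * X[:, 1] + rng.normal(size=278)
        df = pd.DataFrame(np.column_stack([y, X]),
                          columns=["y", "a", "b", "c", "d", "e"])
        rep = stepwise_t2star_model(df, "y", ["a", "b", "c", "d", "e"])
        Xr = (df[list(rep.retained)] - df[list(rep.retained)].mean()) / df[
            list(rep.retained)].std(ddof=1)
        ys = (df["y"] - df["y"].mean()) / df["y"].std(ddof=1)
        fit = sm.OLS(ys, sm.add_constant(Xr)).fit()
        assert (fit.pvalues[1:] <= 0.10 + 1e-12).all()


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_low_direction_matches_exhaustive_sweep_oracle(self):
        scores = np.arange(1.0, 11.0)
        labels = np.isin(scores, [1, 2, 3, 4, 6])
        res = roc_youden(scores, labels, direction="low")
        # oracle: try every observed cutoff c, positive when score <= c
        best = None
        for c in scores:
            sens = np.mean(scores[labels] <= c)
            spec = np.mean(scores[~labels] > c)
            j = sens + spec - 1
            if best is None or j > best[0] or (j == best[0] and sens > best[1]):
                best = (j, sens, spec, c)
        assert res.optimal_cutoff == pytest.approx(best[3])
        assert res.sensitivity == pytest.approx(100 * best[1])
        assert res.specificity == pytest.approx(100 * best[2])

    def test_auc_equals_concordant_pair_count(self, rng):
        scores = rng.integers(0, 8, size=60).astype(float)   # ties on purpose
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = roc_youden(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(conc / (len(pos) * len(neg)), rel=1e-12)

    def test_score_negation_flips_auc(self, rng):
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.3
        labels[0], labels[1] = True, False
        a = roc_youden(scores, labels).auc
        b = roc_youden(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_delong_ci_contains_auc_and_single_class_errors(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.repeat([0, 1], 40)
        res = roc_youden(scores, labels)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high
        assert 0.0 <= res.auc_ci_low and res.auc_ci_high <= 1.0
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_youden(scores, np.ones(80))
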