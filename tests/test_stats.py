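import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from vesselmorph.features import FEATURE_NAMES
from vesselmorph.stats import (
    FORMULAS,
    FormulaError,
    build_formula,
    compare_logistic,
    crossval_r2,
    fit_linear,
    fit_logistic,
    fit_nested_pair,
    label_hypertension,
    nested_anova,
    simulate_subject_table,
    split_by_age,
)


def _vessel_table(n, seed, noise_sd=0.0, coefs=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    tab = pd.DataFrame(X, columns=["total_volume_mm3", "mean_radius_mm", "mean_tortuosity"])
    coefs = coefs if coefs is not None else (2.0, -1.5, 0.5)
    tab["age"] = 10.0 + X @ np.asarray(coefs) + rng.normal(0, noise_sd, n)
    return tab


class TestFormulas:
    def test_nine_formulas_registered(self):
        assert len(FORMULAS) == 9

    def test_expansion_uses_table_columns(self, subject_table):
        f = build_formula("age~cortex+vessels", subject_table)
        for name in FEATURE_NAMES:
            assert name in f
        assert "thickness_region0" in f

    def test_missing_cortex_columns_rejected(self):
        tab = _vessel_table(20, 0)
        with pytest.raises(FormulaError, match="thickness"):
            build_formula("age~cortex", tab)

    def test_dv_formula_requires_dv(self, subject_table):
        with pytest.raises(FormulaError, match="dependent variable"):
            build_formula("dv~age+sex+vessels", subject_table)


class TestFitLinear:
    def test_noiseless_exact_recovery(self):
        tab = _vessel_table(50, 0)
        res = fit_linear(tab, "age~vessels")
        assert res.rsquared_adj == pytest.approx(1.0, abs=1e-10)
        got = {k: v for k, v in res.params.items()}
        assert got["Intercept"] == pytest.approx(10.0, abs=1e-8)
        assert got["total_volume_mm3"] == pytest.approx(2.0, abs=1e-8)
        assert got["mean_radius_mm"] == pytest.approx(-1.5, abs=1e-8)
        assert got["mean_tortuosity"] == pytest.approx(0.5, abs=1e-8)

    def test_coefficient_ci_coverage(self):
        """95% CIs cover the true coefficient at ~nominal rate."""
        hits = np.zeros(3)
        n_rep = 200
        for s in range(n_rep):
            tab = _vessel_table(500, seed=s, noise_sd=3.0)
            ci = fit_linear(tab, "age~vessels").conf_int(alpha=0.05)
            for i, (name, true) in enumerate(
                zip(["total_volume_mm3", "mean_radius_mm", "mean_tortuosity"], (2.0, -1.5, 0.5))
            ):
                lo, hi = ci.loc[name]
                hits[i] += lo <= true <= hi
        assert (hits / n_rep >= 0.93).all()

    def test_constant_response_rejected(self):
        tab = _vessel_table(30, 1)
        tab["age"] = 55.0
        with pytest.raises(FormulaError, match="zero variance"):
            fit_linear(tab, "age~vessels")

    def test_collinear_design_named(self):
        tab = _vessel_table(30, 2)
        tab["mean_tortuosity"] = 2.0 * tab["mean_radius_mm"]
        with pytest.raises(FormulaError, match="collinear"):
            fit_linear(tab, "age~vessels")

    def test_categorical_sex_expanded(self, subject_table):
        res = fit_linear(subject_table, "dv~age+sex+vessels", dv="systolic_bp")
        assert any("C(sex)" in name for name in res.params.index)


class TestNestedAnova:
    def test_matches_anova_lm_oracle_on_random_designs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = rng.integers(60, 200), rng.integers(2, 6)
            X = rng.normal(size=(n, k + 3))
            y = X[:, :k] @ rng.normal(size=k) + rng.normal(size=n)
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(k + 3)])
            df["y"] = y
            red = sm.OLS(df["y"], sm.add_constant(df.iloc[:, :k])).fit()
            full = sm.OLS(df["y"], sm.add_constant(df.iloc[:, : k + 3])).fit()
            mine = nested_anova(red, full)
            oracle = anova_lm(red, full)
            assert mine.f_statistic == pytest.approx(oracle["F"].iloc[1], abs=1e-8)
            assert mine.p_value == pytest.approx(oracle["Pr(>F)"].iloc[1], abs=1e-10)
            assert mine.df_num == 3

    def test_orthogonal_useless_predictors_give_f_zero(self):
        """Added columns orthogonal to the residual leave SSR unchanged."""
        rng = np.random.default_rng(3)
        n = 80
        X = rng.normal(size=(n, 3))
        y = X @ (1.0, 2.0, -1.0) + rng.normal(size=n)
        red = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=list("abc")))).fit()
        basis = np.column_stack([np.ones(n), X, red.resid])
        Z = rng.normal(size=(n, 2))
        Z -= basis @ np.linalg.lstsq(basis, Z, rcond=None)[0]
        full_X = sm.add_constant(
            pd.DataFrame(np.column_stack([X, Z]), columns=list("abcde"))
        )
        full = sm.OLS(y, full_X).fit()
        cmp_ = nested_anova(red, full)
        assert cmp_.f_statistic == pytest.approx(0.0, abs=1e-8)
        assert cmp_.p_value == pytest.approx(1.0, abs=1e-8)

    def test_non_nested_rejected(self):
        tab = simulate_subject_table(n=100, seed=1)
        a = fit_linear(tab, "age~vessels")
        b = fit_linear(tab, "age~cortex")
        with pytest.raises(FormulaError, match="not nested"):
            nested_anova(a, b)

    def test_row_mismatch_rejected(self, subject_table):
        red = fit_linear(subject_table, "age~cortex")
        full = fit_linear(subject_table.iloc[:-5], "age~cortex+vessels")
        with pytest.raises(FormulaError, match="different numbers of rows"):
            nested_anova(red, full)

    def test_eleven_feature_df_bookkeeping(self):
        """Adding the 11 vessel features gives df_num = 11 and
        df_den = n - p_full, the denominator structure of the cohort ANOVA."""
        tab = simulate_subject_table(n=655, seed=4)
        cmp_ = fit_nested_pair(tab, "age~cortex", "age~cortex+vessels")
        assert cmp_.df_num == 11
        n_params_full = 1 + 6 + 11  # intercept + thickness regions + vessel features
        assert cmp_.df_den == 655 - n_params_full
        assert cmp_.adj_r2_full >= cmp_.adj_r2_reduced

    def test_in_sample_r2_monotone_under_added_regressors(self, subject_table):
        red = fit_linear(subject_table, "age~cortex")
        full = fit_linear(subject_table, "age~cortex+vessels")
        assert full.rsquared >= red.rsquared


class TestCrossVal:
    def test_noiseless_r2_near_one(self):
        tab = _vessel_table(200, 5)
        cv = crossval_r2(tab, "age~vessels", k=10, seed=0)
        assert cv.r2 > 0.999

    def test_null_r2_small(self):
        worst = -np.inf
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tab = _vessel_table(500, seed)
            tab["age"] = rng.normal(size=len(tab))  # independent of the features
            worst = max(worst, crossval_r2(tab, "age~vessels", k=10, seed=seed).r2)
        assert worst <= 0.05

    def test_same_seed_identical(self, subject_table):
        a = crossval_r2(subject_table, "age~cortex+vessels", k=10, seed=7)
        b = crossval_r2(subject_table, "age~cortex+vessels", k=10, seed=7)
        assert a.r2 == b.r2
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_every_subject_predicted_once(self, subject_table):
        cv = crossval_r2(subject_table, "age~vessels", k=10, seed=0)
        counts = np.bincount(cv.fold_assignment, minlength=10)
        assert counts.sum() == len(subject_table.dropna())
        assert (counts > 0).all()

    def test_too_many_folds_rejected(self):
        tab = _vessel_table(8, 0)
        with pytest.raises(ValueError):
            crossval_r2(tab, "age~vessels", k=20, seed=0)


class TestHypertension:
    @pytest.mark.parametrize(
        "dbp,sbp,expected",
        [
            (95, 120, True),
            (85, 135, False),
            (90, 140, False),  # thresholds are strict ("above")
            (90.1, 140, True),
            (90, 140.1, True),
            (91, 141, True),
            (60, 100, False),
        ],
    )
    def test_rule_truth_table(self, dbp, sbp, expected):
        assert label_hypertension(dbp, sbp) is expected

    def test_missing_values_yield_missing_label(self):
        lab = label_hypertension([95.0, np.nan], [120.0, 130.0])
        assert bool(lab.iloc[0]) is True
        assert lab.iloc[1] is pd.NA

    def test_prevalence_matches_normal_exceedance(self):
        """Labels from simulated normal BPs match the closed-form rate."""
        from scipy.stats import norm

        rng = np.random.default_rng(9)
        n = 200_000
        d = rng.normal(80, 10, n)
        s = rng.normal(125, 15, n)
        lab = label_hypertension(d, s)
        p_d, p_s = norm.sf(90, 80, 10), norm.sf(140, 125, 15)
        expect = p_d + p_s - p_d * p_s  # independent OR rule
        mc_sd = np.sqrt(expect * (1 - expect) / n)
        assert abs(lab.mean() - expect) < 4 * mc_sd

    def test_age_split_boundary(self):
        tab = pd.DataFrame({"age": [59.0, 60.0, 60.5, 75.0]})
        older, younger = split_by_age(tab)
        assert older["age"].tolist() == [60.5, 75.0]
        assert younger["age"].tolist() == [59.0, 60.0]


class TestLogistic:
    def test_single_class_outcome_rejected(self, subject_table):
        tab = subject_table.copy()
        tab["hypertension"] = False
        with pytest.raises(FormulaError, match="single-class"):
            fit_logistic(tab, "htn~age+sex+vessels")

    def test_vessel_feature_effect_detected(self):
        """When hypertension depends on one vessel feature, the augmented
        model wins the likelihood-ratio test in >= 95% of seeds."""
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            tab = simulate_subject_table(n=400, seed=seed)
            rng = np.random.default_rng(seed + 10_000)
            logit = -2.0 + 3.0 * (
                (tab["mean_radius_mm"] - tab["mean_radius_mm"].mean())
                / tab["mean_radius_mm"].std()
            )
            tab["hypertension"] = rng.random(len(tab)) < 1 / (1 + np.exp(-logit))
            cmp_ = compare_logistic(tab, "htn~age+sex+cortex", "htn~age+sex+cortex+vessels")
            wins += cmp_.lrt_p_value < 0.01
        assert wins / n_rep >= 0.95

    def test_df_bookkeeping(self, subject_table):
        cmp_ = compare_logistic(
            subject_table, "htn~age+sex+cortex", "htn~age+sex+cortex+vessels"
        )
        assert cmp_.df_num == 11
        assert cmp_.lrt_chi2 >= 0.0
        assert 0.0 <= cmp_.p_value <= 1.0

    def test_perfect_separation_flagged_not_raised(self):
        rng = np.random.default_rng(11)
        tab = simulate_subject_table(n=120, seed=11)
        tab["hypertension"] = tab["mean_radius_mm"] > tab["mean_radius_mm"].median()
        with pytest.warns():
            res = fit_logistic(tab, "htn~age+sex+vessels")
        assert hasattr(res, "perfectly_separated")
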