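"""Linear/logistic fits, interaction wrappers and the additive-scale table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endoprs.icd import CodeSet, burden_table
from endoprs.interactions import (
    RankDeficientError,
    additive_interaction,
    burden_prs_interaction,
    decile_difference_ratio,
    fit_logistic,
    fit_ols,
    multiplicative_interaction,
    welch_t,
)
from endoprs.prs import assign_quantiles
from endoprs.simulate import Cohort


class TestOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        design = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = fit_ols(2 + 3 * x, design)
        assert fit.coef["intercept"] == pytest.approx(2.0)
        assert fit.coef["x"] == pytest.approx(3.0)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        y = rng.normal(size=6)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        fit = fit_ols(y, pd.DataFrame(X, columns=["intercept", "a", "b"]))
        for i, term in enumerate(["intercept", "a", "b"]):
            assert fit.coef[term] == pytest.approx(beta[i], abs=1e-10)
            assert fit.se[term] == pytest.approx(se[i], abs=1e-10)

    def test_duplicated_column_named_in_error(self):
        x = np.arange(5.0)
        design = pd.DataFrame({"intercept": 1.0, "x": x, "x_copy": x})
        with pytest.raises(RankDeficientError, match="x"):
            fit_ols(x, design)


class TestLogistic:
    def test_grouped_2x2_closed_form(self):
        # cells: exposed (10 cases, 5 non), unexposed (20 cases, 40 non)
        x = np.array([1.0] * 15 + [0.0] * 60)
        y = np.array([1.0] * 10 + [0.0] * 5 + [1.0] * 20 + [0.0] * 40)
        fit = fit_logistic(y, pd.DataFrame({"intercept": 1.0, "x": x}))
        assert fit.converged
        assert fit.coef["x"] == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.coef["intercept"] == pytest.approx(np.log(20 / 40), abs=1e-6)

    def test_null_slope_and_intercept(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([np.ones(500), -np.ones(500)])
        y = np.tile([1.0, 0.0, 0.0, 0.0], 250)  # prevalence 0.25, independent of x
        fit = fit_logistic(y, pd.DataFrame({"intercept": 1.0, "x": x}))
        assert fit.coef["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.coef["intercept"] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = (x > 2.5).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"intercept": 1.0, "x": x}))
        assert not fit.converged
        assert np.isnan(fit.coef["x"])

    def test_weak_effect_logistic_vs_linear_probability(self):
        # at prevalence 0.5, logistic slope ~ 4x the linear-probability slope
        rng = np.random.default_rng(10)
        n = 50_000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.0 + 0.1 * x)))
        y = (rng.random(n) < p).astype(float)
        design = pd.DataFrame({"intercept": 1.0, "x": x})
        logit = fit_logistic(y, design)
        ols = fit_ols(y, design)
        assert 3.5 < logit.coef["x"] / ols.coef["x"] < 4.5


class TestWelch:
    def test_identical_samples(self):
        t, _, p, _, _ = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        # va=vb=1, n=3 each: se^2 = 2/3, t = -3/sqrt(2/3), df = 4 exactly
        t, df, p, ma, mb = welch_t(a, b)
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-10)
        assert df == pytest.approx(4.0, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(3 / np.sqrt(2 / 3), 4), abs=1e-10)
        assert (ma, mb) == (2.0, 5.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        t1, df1, p1, *_ = welch_t(a, b)
        t2, df2, p2, *_ = welch_t(10 * a, 10 * b)
        assert t1 == pytest.approx(t2, rel=1e-12)
        assert df1 == pytest.approx(df2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestBurdenInteractionWrapper:
    def test_delegates_to_ols_exactly(self, sim_cohort, index_code_set):
        bt = burden_table(sim_cohort.diagnoses, sim_cohort.ids, index_code_set)
        fit = burden_prs_interaction(sim_cohort, bt, metric="comorbid", resolution=3)
        ph = sim_cohort.phenotypes.set_index("id")
        prs = ph["prs_z"].to_numpy(float)
        endo = ph["endo_case"].to_numpy(float)
        design = pd.DataFrame(
            {"intercept": 1.0, "prs": prs, "endo": endo, "prs_x_endo": prs * endo}
        )
        manual = fit_ols(bt["comorbid_3char"].reindex(ph.index).to_numpy(float), design)
        for term in fit.terms:
            assert fit.coef[term] == pytest.approx(manual.coef[term], abs=1e-12)
            assert fit.se[term] == pytest.approx(manual.se[term], abs=1e-12)

    def test_leave_one_out_scope_identity(self, sim_cohort, index_code_set):
        bt = burden_table(sim_cohort.diagnoses, sim_cohort.ids, index_code_set)
        fit_all = burden_prs_interaction(sim_cohort, bt, metric="total", scope="all")
        # chapter + leave-one-out responses sum to the full response
        y_ch = bt["ch11_total"]
        y_loo = bt["total_3char"] - bt["ch11_total"]
        assert ((y_ch + y_loo) == bt["total_3char"]).all()
        fit_loo = burden_prs_interaction(
            sim_cohort, bt, metric="total", scope=("leave_out", 11)
        )
        assert fit_loo.n == fit_all.n


class TestMultiplicativeWrapper:
    def test_delegates_to_logistic(self, sim_cohort):
        fit = multiplicative_interaction(sim_cohort, "uterine_fibroids")
        ph = sim_cohort.phenotypes.set_index("id")
        com = sim_cohort.comorbidity_flags["uterine_fibroids"].reindex(ph.index)
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "prs": ph["prs_z"].to_numpy(float),
                "com": com.to_numpy(float),
                "prs_x_com": ph["prs_z"].to_numpy(float) * com.to_numpy(float),
            }
        )
        manual = fit_logistic(ph["endo_case"].to_numpy(float), design)
        assert fit.converged and manual.converged
        for term in fit.terms:
            assert fit.coef[term] == pytest.approx(manual.coef[term], abs=1e-10)

    def test_positive_main_effects_under_shared_factors(self, sim_cohort):
        fit = multiplicative_interaction(sim_cohort, "uterine_fibroids")
        assert fit.coef["prs"] > 0 and fit.p["prs"] < 0.05
        assert fit.coef["com"] > 0 and fit.p["com"] < 0.05

    def test_constant_flag_rank_error(self, tiny_cohort):
        tiny_cohort.comorbidity_flags["always"] = True
        with pytest.raises(RankDeficientError):
            multiplicative_interaction(tiny_cohort, "always")


class TestAdditiveInteraction:
    def test_printed_decile_ratio_convention(self):
        # worked example: differences of 5.67 and 15.57 percentage points
        assert decile_difference_ratio(5.67, 15.57) == 2.7

    def test_per_decile_differences(self, sim_cohort):
        scores = sim_cohort.phenotypes.set_index("id")["prs_z"]
        deciles = assign_quantiles(scores, k=10)
        tab = additive_interaction(sim_cohort, "uterine_fibroids", deciles)
        ok = tab[~tab["flagged"]]
        assert np.allclose(
            ok["difference_pp"],
            100 * (ok["prevalence_with"] - ok["prevalence_without"]),
        )
        assert ((ok["prevalence_with"].between(0, 1)) & (ok["prevalence_without"].between(0, 1))).all()

    def test_differences_trend_with_decile(self, sim_cohort):
        from scipy.stats import spearmanr

        scores = sim_cohort.phenotypes.set_index("id")["prs_z"]
        deciles = assign_quantiles(scores, k=10)
        tab = additive_interaction(sim_cohort, "uterine_fibroids", deciles)
        res = spearmanr(tab.index, tab["difference_pp"])
        assert res.statistic > 0
        assert res.pvalue < 0.05

    def test_empty_arm_flagged(self):
        ph = pd.DataFrame(
            {"id": [f"i{j}" for j in range(20)],
             "endo_case": [True, False] * 10,
             "age": [40.0] * 20,
             "prs_z": np.arange(20.0)}
        )
        flags = pd.DataFrame(
            {"c": [False] * 10 + [True] * 10},
            index=pd.Index(ph["id"], name="id"),
        )
        cohort = Cohort(ph, pd.DataFrame({"id": [], "code": []}), flags)
        deciles = assign_quantiles(ph.set_index("id")["prs_z"], k=2)
        tab = additive_interaction(cohort, "c", deciles)
        assert tab.loc[1, "flagged"]  # bottom half has no comorbidity carriers
        assert np.isnan(tab.attrs["ratio_top_vs_bottom"])


class TestArtifactReproduction:
    def test_additive_ratio_and_negative_multiplicative_coexist(self, big_artifact_cohort):
        """Under one threshold-model parameterization the additive-scale
        difference ratio exceeds 1 while the multiplicative interaction is
        non-positive: the multiplicative 'antagonism' is a baseline-risk
        artifact, not a mechanistic interaction."""
        cohort = big_artifact_cohort
        scores = cohort.phenotypes.set_index("id")["prs_z"]
        deciles = assign_quantiles(scores, k=10)
        tab = additive_interaction(cohort, "uterine_fibroids", deciles)
        assert tab.attrs["ratio_top_vs_bottom"] > 1
        fit = multiplicative_interaction(cohort, "uterine_fibroids")
        assert fit.converged
        assert fit.coef["prs_x_com"] <= 0
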