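"""Scoring, standardization, quantile stratification, AUC and prevalence tables."""

import numpy as np
import pandas as pd
import pytest

from endoprs.prs import (
    QuantileAssignment,
    ScoringError,
    assign_quantiles,
    or_by_quantile,
    prevalence_by_burden,
    roc_auc,
    score_genotypes,
    standardize_scores,
)
from endoprs.simulate import Cohort, SimulationParams, simulate_cohort


def brute_force_auc(scores, status):
    """Pairwise concordance probability (ties count half)."""
    scores = np.asarray(scores, float)
    status = np.asarray(status, bool)
    cases, controls = scores[status], scores[~status]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestScoring:
    def _dosages(self, values, snps=("rs1",)):
        return pd.DataFrame(values, index=[f"i{j}" for j in range(len(values))],
                            columns=list(snps))

    def test_average_per_allele_convention(self):
        # sum(w * dosage) / (2 * n_snps): one SNP, weight 1 -> dosage / 2
        dosages = self._dosages([[0], [1], [2]])
        weights = pd.DataFrame({"snp_id": ["rs1"], "effect_allele": ["A"], "weight": [1.0]})
        raw = score_genotypes(dosages, weights)
        assert raw.tolist() == [0.0, 0.5, 1.0]

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        dosages = self._dosages(rng.integers(0, 3, (20, 3)), snps=["rs1", "rs2", "rs3"])
        weights = pd.DataFrame(
            {"snp_id": ["rs1", "rs2", "rs3"], "effect_allele": list("ACG"),
             "weight": [0.5, -1.0, 2.0]}
        )
        doubled = weights.assign(weight=weights["weight"] * 2)
        assert np.allclose(
            2 * score_genotypes(dosages, weights), score_genotypes(dosages, doubled)
        )

    def test_missing_snp_errors(self):
        dosages = self._dosages([[0], [1]])
        weights = pd.DataFrame(
            {"snp_id": ["rs1", "rs99"], "effect_allele": ["A", "C"], "weight": [1.0, 1.0]}
        )
        with pytest.raises(ScoringError, match="rs99"):
            score_genotypes(dosages, weights)

    def test_missing_dosage_frequency_imputation(self):
        dosages = self._dosages([[np.nan], [2.0]])
        weights = pd.DataFrame(
            {"snp_id": ["rs1"], "effect_allele": ["A"], "weight": [1.0], "freq": [0.25]}
        )
        raw = score_genotypes(dosages, weights)
        assert raw.iloc[0] == pytest.approx(2 * 0.25 / 2)  # imputed to 2f

    def test_missing_dosage_drop_adjusts_divisor(self):
        dosages = self._dosages([[np.nan, 2.0], [2.0, 2.0]], snps=["rs1", "rs2"])
        weights = pd.DataFrame(
            {"snp_id": ["rs1", "rs2"], "effect_allele": ["A", "C"], "weight": [1.0, 1.0]}
        )
        raw = score_genotypes(dosages, weights)
        assert raw.iloc[0] == pytest.approx(2.0 / 2)   # one SNP scored, divisor 2
        assert raw.iloc[1] == pytest.approx(4.0 / 4)


class TestStandardize:
    def test_two_point_hand_calc(self):
        z = standardize_scores(pd.Series([0.0, 1.0]))
        assert np.allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_errors(self):
        with pytest.raises(ScoringError):
            standardize_scores(pd.Series([1.0, 1.0, 1.0]))

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        z = standardize_scores(pd.Series(rng.normal(5, 3, 1000)))
        assert abs(z.mean()) < 1e-8
        assert abs(z.var(ddof=1) - 1) < 1e-8


class TestQuantiles:
    def test_equal_bins(self):
        scores = pd.Series(np.arange(100.0), index=[f"i{j}" for j in range(100)])
        a = assign_quantiles(scores, k=10)
        assert a.bins.value_counts().eq(10).all()
        assert a.bins.min() == 1 and a.bins.max() == 10

    def test_ties_stable_with_warning(self):
        scores = pd.Series(np.zeros(100), index=[f"i{j}" for j in range(100)])
        with pytest.warns(UserWarning, match="tied"):
            a = assign_quantiles(scores, k=10)
        assert a.bins.value_counts().eq(10).all()

    def test_biobank_scale_centiles(self):
        rng = np.random.default_rng(2)
        n = 97_776  # 5,432 + 92,344
        scores = pd.Series(rng.normal(size=n), index=[f"i{j}" for j in range(n)])
        a = assign_quantiles(scores, k=100)
        sizes = a.bins.value_counts()
        assert set(sizes.unique()) == {977, 978}
        assert len(sizes) == 100

    def test_ranks_respect_scores(self):
        scores = pd.Series([3.0, -1.0, 2.0, 0.0], index=list("abcd"))
        a = assign_quantiles(scores, k=4)
        assert a.bins.sort_values().index.tolist() == ["b", "d", "c", "a"]


class TestOrByQuantile:
    def _assignment(self, bins, ids):
        return QuantileAssignment(
            bins=pd.Series(bins, index=ids), k=max(bins), bin_edges=np.array([])
        )

    def test_reference_or_is_one(self):
        ids = [f"i{j}" for j in range(40)]
        a = self._assignment([1] * 20 + [2] * 20, ids)
        status = pd.Series([True] * 5 + [False] * 15 + [True] * 10 + [False] * 10, index=ids)
        out = or_by_quantile(a, status, reference_bin=1)
        assert out.loc[1, "odds_ratio"] == 1.0
        assert (out.loc[1, ["ci_low", "ci_high"]] == 1.0).all()

    def test_hand_computed_or(self):
        ids = [f"i{j}" for j in range(200)]
        bins = [1] * 100 + [2] * 100
        status = pd.Series([True] * 10 + [False] * 90 + [True] * 20 + [False] * 80, index=ids)
        out = or_by_quantile(self._assignment(bins, ids), status, reference_bin=1)
        assert out.loc[2, "odds_ratio"] == pytest.approx((20 * 90) / (80 * 10))

    def test_degenerate_reference_errors(self):
        ids = list("abcd")
        a = self._assignment([1, 1, 2, 2], ids)
        status = pd.Series([False, False, True, False], index=ids)
        with pytest.raises(ValueError, match="reference"):
            or_by_quantile(a, status, reference_bin=1)

    def test_decile_ors_monotone_in_simulation(self):
        from scipy.stats import spearmanr

        params = SimulationParams(
            n_individuals=200_000, prs_r2=0.26, shared_factor_loading_endo=0.0,
            background_rate=0.0, seed=17,
        )
        cohort = simulate_cohort(params)
        scores = cohort.phenotypes.set_index("id")["prs_z"]
        a = assign_quantiles(scores, k=10)
        out = or_by_quantile(a, cohort.phenotypes.set_index("id")["endo_case"])
        rho = spearmanr(out.index, out["odds_ratio"]).statistic
        assert rho > 0.9


class TestAUC:
    def test_constant_scores(self):
        assert roc_auc([1.0] * 10, [True] * 5 + [False] * 5) == 0.5

    def test_hand_example(self):
        assert roc_auc([1, 3, 0, 2], [True, True, False, False]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([2, 3, 0, 1], [True, True, False, False]) == 1.0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(6, 30)
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], n)
            status = np.zeros(n, bool)
            status[: rng.integers(1, n - 1)] = True
            assert roc_auc(scores, status) == pytest.approx(
                brute_force_auc(scores, status), abs=0
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=500)
        status = rng.random(500) < 0.3
        assert roc_auc(scores, status) == pytest.approx(
            roc_auc_score(status, scores), abs=1e-12
        )

    def test_rank_invariance_under_standardization(self):
        rng = np.random.default_rng(6)
        raw = pd.Series(rng.normal(3, 7, 400))
        status = rng.random(400) < 0.4
        assert roc_auc(raw, status) == roc_auc(standardize_scores(raw), status)


class TestPrevalenceByBurden:
    def _cohort(self, counts, case):
        n = len(counts)
        ph = pd.DataFrame(
            {"id": [f"i{j}" for j in range(n)], "endo_case": case,
             "age": [40.0] * n, "prs_z": [0.0] * n}
        )
        burden = pd.Series(counts, index=ph["id"].to_numpy())
        return Cohort(ph, pd.DataFrame({"id": [], "code": []})), burden

    def test_perfectly_stratified(self):
        cohort, burden = self._cohort([5, 5, 0, 0], [True, True, False, False])
        out = prevalence_by_burden(cohort, burden).set_index("count")
        assert out.loc[5, "prevalence"] == 1.0
        assert out.loc[0, "prevalence"] == 0.0

    def test_empty_groups_omitted(self):
        cohort, burden = self._cohort([0, 0, 3, 3], [False, True, False, True])
        out = prevalence_by_burden(cohort, burden)
        assert set(out["count"]) == {0, 3}

    def test_flat_when_independent(self):
        rng = np.random.default_rng(7)
        n = 20_000
        counts = rng.poisson(3, n)
        case = rng.random(n) < 0.1
        cohort, burden = self._cohort(counts, case)
        out = prevalence_by_burden(cohort, burden, cap=8)
        big = out[out["n"] > 500]
        # slope of prevalence on count should be ~0: weighted regression check
        w = big["n"].to_numpy(float)
        x, y = big["count"].to_numpy(float), big["prevalence"].to_numpy(float)
        slope = np.polyfit(x, y, 1, w=np.sqrt(w))[0]
        assert abs(slope) < 0.01

    def test_cap_pools_top_groups(self):
        cohort, burden = self._cohort([0, 1, 7, 9], [False, False, True, True])
        out = prevalence_by_burden(cohort, burden, cap=5)
        assert out["count"].max() == 5
        assert out.set_index("count").loc[5, "n"] == 2
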