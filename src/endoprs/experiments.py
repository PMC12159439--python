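"""Reference experiments: the study conditions the package is validated under.

Each function runs one documented simulation study end to end and returns
plain data structures, so the same computations back both the test suite
and the reproduction script. Problem sizes are the documented defaults of
each study (see docs/methods.md); all randomness is controlled by explicit
seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .icd import CodeSet, burden_table
from .interactions import burden_prs_interaction, fit_logistic
from .prs import roc_auc
from .scan import phenome_scan
from .simulate import SimulationParams, collider_default_params, simulate_cohort

__all__ = [
    "collider_signature",
    "null_scan_false_positives",
    "interaction_null_coverage",
    "auc_by_variance_explained",
]


def collider_signature(
    seeds=range(1, 11), n_individuals: int = 200_000
) -> pd.DataFrame:
    """Index-event (collider) signature across replicate cohorts.

    For each seed, simulates the default collider cohort (20 comorbid
    conditions sharing a latent factor with the index disease), counts
    comorbid burden against the true index-code set, and fits
    burden ~ PRS + status + PRS x status. Returns one row per seed with the
    interaction coefficient and the within-arm PRS-burden correlations.
    """
    rows = []
    for seed in seeds:
        params = collider_default_params(seed=seed, n_individuals=n_individuals)
        cohort = simulate_cohort(params)
        code_set = CodeSet(
            frozenset(s.icd_code for s in params.comorbidities), 4, label="index"
        )
        table = burden_table(cohort.diagnoses, cohort.ids, code_set)
        fit = burden_prs_interaction(cohort, table, metric="comorbid", resolution=3)
        burden = table["comorbid_3char"].reindex(cohort.ids).to_numpy(dtype=float)
        case = cohort.status
        rows.append(
            {
                "seed": seed,
                "interaction": fit.coef["prs_x_endo"],
                "interaction_se": fit.se["prs_x_endo"],
                "interaction_p": fit.p["prs_x_endo"],
                "corr_controls": float(np.corrcoef(cohort.prs_z[~case], burden[~case])[0, 1]),
                "corr_cases": float(np.corrcoef(cohort.prs_z[case], burden[case])[0, 1]),
            }
        )
    return pd.DataFrame(rows)


def null_scan_false_positives(
    n_reps: int = 100,
    n_individuals: int = 50_000,
    base_seed: int = 1000,
    q: float = 0.05,
) -> pd.DataFrame:
    """FDR behavior of the phenome scan when every code is null.

    Cohorts carry only background diagnoses (about 200 distinct codes drawn
    independently of status), so every rejection is a false positive.
    Returns per-replicate tested/significant counts; under
    Benjamini-Hochberg both the expected significant fraction and the
    false-discovery proportion are bounded by ``q``.

    The per-replicate cohort size keeps expected contingency-cell counts
    near 50, where the chi-squared approximation is accurate in the deep
    tail that the step-up procedure actually thresholds (p ~ q/m); much
    smaller cohorts inflate false positives through the test statistic, not
    through the multiplicity procedure.
    """
    rows = []
    for rep in range(n_reps):
        params = SimulationParams(
            n_individuals=n_individuals,
            background_rate=4.0,
            chapter_pool_sizes={ch: 12 for ch in range(1, 18)},
            seed=base_seed + rep,
        )
        scan = phenome_scan(simulate_cohort(params), q=q)
        rows.append(
            {
                "rep": rep,
                "n_tested": scan.n_tested,
                "n_significant": scan.n_significant,
                "fraction_significant": scan.n_significant / max(scan.n_tested, 1),
                "fdp": 1.0 if scan.n_significant else 0.0,
            }
        )
    return pd.DataFrame(rows)


def interaction_null_coverage(
    n_reps: int = 1_000,
    n_individuals: int = 4_000,
    base_seed: int = 2_000,
    level: float = 0.95,
) -> pd.DataFrame:
    """CI calibration of the multiplicative interaction under a logistic null.

    Outcomes are generated directly from a logistic model with main effects
    for the score and the comorbidity but a zero product term, so the
    fitted interaction's CI should cover 0 at its nominal rate. The
    replicate count is set so Monte-Carlo noise in the coverage estimate
    (SE ~ 0.7 percentage points) is small against the nominal 95%.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep)
        prs = rng.standard_normal(n_individuals)
        com = (rng.random(n_individuals) < 0.2).astype(float)
        linpred = -1.5 + 0.5 * prs + 0.8 * com
        y = (rng.random(n_individuals) < 1.0 / (1.0 + np.exp(-linpred))).astype(float)
        design = pd.DataFrame(
            {"intercept": 1.0, "prs": prs, "com": com, "prs_x_com": prs * com}
        )
        fit = fit_logistic(y, design)
        lo, hi = fit.ci("prs_x_com", level) if fit.converged else (np.nan, np.nan)
        rows.append(
            {
                "rep": rep,
                "converged": fit.converged,
                "estimate": fit.coef["prs_x_com"],
                "covers_zero": bool(fit.converged and lo <= 0.0 <= hi),
            }
        )
    return pd.DataFrame(rows)


def auc_by_variance_explained(
    r2_values=(0.0, 0.05, 0.26), n_individuals: int = 200_000, seed: int = 7
) -> dict[float, float]:
    """Realized PRS discrimination (AUC) as liability variance explained grows."""
    out = {}
    for r2 in r2_values:
        params = SimulationParams(
            n_individuals=n_individuals,
            prs_r2=r2,
            shared_factor_loading_endo=0.0,
            background_rate=0.0,
            seed=seed,
        )
        cohort = simulate_cohort(params)
        out[r2] = roc_auc(cohort.prs_z, cohort.status)
    return out
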