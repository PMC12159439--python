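"""Interaction analyses between polygenic score, case status and comorbidity.

Three complementary analyses:

* a linear model of comorbidity burden on PRS, case status and their
  product — the negative product term among cases is the index-event
  (collider) signature;
* a logistic model of case status on PRS, comorbidity presence and their
  product — interaction on the multiplicative (log-odds) scale;
* a decile-stratified table of absolute prevalence differences with versus
  without a comorbidity — interaction on the additive scale, summarized by
  the ratio of the top-decile to bottom-decile difference.

Model fits delegate to statsmodels (OLS with classical standard errors;
logistic MLE by Newton iteration with separation detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning
import warnings

from .prs import QuantileAssignment, _wilson_ci
from .simulate import Cohort

__all__ = [
    "LinearFit",
    "LogisticFit",
    "RankDeficientError",
    "fit_ols",
    "fit_logistic",
    "burden_prs_interaction",
    "multiplicative_interaction",
    "additive_interaction",
    "welch_t",
]


class RankDeficientError(ValueError):
    pass


@dataclass
class LinearFit:
    """OLS coefficients with classical (homoskedastic) inference."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    tstat: dict[str, float]
    p: dict[str, float]
    n: int
    resid_var: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.coef[t] for t in self.terms],
                "se": [self.se[t] for t in self.terms],
                "stat": [self.tstat[t] for t in self.terms],
                "p": [self.p[t] for t in self.terms],
            }
        )


@dataclass
class LogisticFit:
    """Logistic MLE; coefficients withheld when separation is detected."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    zstat: dict[str, float]
    p: dict[str, float]
    n: int
    converged: bool
    iterations: int = 0

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.coef[term] - z * self.se[term], self.coef[term] + z * self.se[term])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.coef[t] for t in self.terms],
                "se": [self.se[t] for t in self.terms],
                "stat": [self.zstat[t] for t in self.terms],
                "p": [self.p[t] for t in self.terms],
            }
        )


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        collinear = []
        cols = list(design.columns)
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(cols[j])
        raise RankDeficientError(f"design is rank deficient; collinear columns: {collinear}")


def fit_ols(response, design: pd.DataFrame) -> LinearFit:
    """Least squares with classical SEs and two-sided t-test p-values."""
    y = np.asarray(response, dtype=float)
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than design columns")
    _check_rank(design)
    res = sm.OLS(y, design).fit()
    terms = list(design.columns)
    return LinearFit(
        terms=terms,
        coef=dict(zip(terms, res.params)),
        se=dict(zip(terms, res.bse)),
        tstat=dict(zip(terms, res.tvalues)),
        p=dict(zip(terms, res.pvalues)),
        n=len(y),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
    )


def fit_logistic(outcome, design: pd.DataFrame, maxiter: int = 100) -> LogisticFit:
    """Logistic regression MLE (Newton), flagging separation.

    On (quasi-)separation the likelihood has no finite maximizer; the fit is
    returned with ``converged=False`` and NaN coefficients rather than a
    spuriously large number.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes required")
    _check_rank(design)
    terms = list(design.columns)
    nan = {t: np.nan for t in terms}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(method="newton", maxiter=maxiter, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(terms, nan, nan, nan, nan, n=len(y), converged=False)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or np.abs(res.params).max() > 50:
        return LogisticFit(
            terms, nan, nan, nan, nan, n=len(y), converged=False,
            iterations=int(res.mle_retvals.get("iterations", 0)),
        )
    return LogisticFit(
        terms=terms,
        coef=dict(zip(terms, res.params)),
        se=dict(zip(terms, res.bse)),
        zstat=dict(zip(terms, res.tvalues)),
        p=dict(zip(terms, res.pvalues)),
        n=len(y),
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", 0)),
    )


def _burden_column(metric: str, resolution: int, scope: str | tuple[str, int]) -> str:
    if metric not in ("total", "comorbid"):
        raise ValueError("metric must be 'total' or 'comorbid'")
    if scope == "all":
        if resolution not in (3, 4):
            raise ValueError("resolution must be 3 or 4")
        return f"{metric}_{resolution}char"
    kind, ch = scope
    if resolution != 3:
        raise ValueError("chapter-scoped burdens are defined at 3-character resolution")
    if kind not in ("chapter", "leave_out") or not 1 <= ch <= 22:
        raise ValueError(f"bad scope: {scope!r}")
    return f"ch{ch}_{metric}"


def burden_prs_interaction(
    cohort: Cohort,
    burden_table: pd.DataFrame,
    metric: str = "comorbid",
    resolution: int = 3,
    scope: str | tuple[str, int] = "all",
) -> LinearFit:
    """Linear model: burden ~ PRS + status + PRS x status.

    ``scope`` is ``"all"``, ``("chapter", c)`` or ``("leave_out", c)``;
    chapter scopes use 3-character counts. Leave-one-out counts are the
    full 3-character count minus the chapter's count.
    """
    col = _burden_column(metric, resolution if scope == "all" else 3, scope)
    ph = cohort.phenotypes.set_index("id")
    y = burden_table[col] if scope == "all" or scope[0] == "chapter" else (
        burden_table[f"{metric}_3char"] - burden_table[col]
    )
    y = y.reindex(ph.index)
    if y.isna().any():
        raise ValueError("burden table does not cover the cohort")
    prs = ph["prs_z"].to_numpy(dtype=float)
    endo = ph["endo_case"].to_numpy(dtype=float)
    design = pd.DataFrame(
        {"intercept": 1.0, "prs": prs, "endo": endo, "prs_x_endo": prs * endo}
    )
    return fit_ols(y.to_numpy(dtype=float), design)


def interaction_scan_by_chapter(
    cohort: Cohort, burden_table: pd.DataFrame, metric: str = "comorbid"
) -> pd.DataFrame:
    """The PRS x status term for every chapter scope and leave-one-out scope."""
    rows = []
    for kind in ("chapter", "leave_out"):
        for ch in range(1, 23):
            try:
                fit = burden_prs_interaction(
                    cohort, burden_table, metric=metric, resolution=3, scope=(kind, ch)
                )
                rows.append(
                    {
                        "scope": kind,
                        "chapter": ch,
                        "estimate": fit.coef["prs_x_endo"],
                        "se": fit.se["prs_x_endo"],
                        "p": fit.p["prs_x_endo"],
                    }
                )
            except RankDeficientError:
                rows.append(
                    {"scope": kind, "chapter": ch, "estimate": np.nan, "se": np.nan, "p": np.nan}
                )
    return pd.DataFrame(rows)


def multiplicative_interaction(cohort: Cohort, comorbidity_name: str) -> LogisticFit:
    """Logistic model: status ~ PRS + comorbidity + PRS x comorbidity."""
    if cohort.comorbidity_flags is None or comorbidity_name not in cohort.comorbidity_flags:
        raise KeyError(f"no comorbidity flags for {comorbidity_name!r}")
    ph = cohort.phenotypes.set_index("id")
    com = cohort.comorbidity_flags[comorbidity_name].reindex(ph.index).to_numpy(dtype=float)
    prs = ph["prs_z"].to_numpy(dtype=float)
    y = ph["endo_case"].to_numpy(dtype=float)
    design = pd.DataFrame(
        {"intercept": 1.0, "prs": prs, "com": com, "prs_x_com": prs * com}
    )
    return fit_logistic(y, design)


def additive_interaction(
    cohort: Cohort, comorbidity_name: str, assignment: QuantileAssignment
) -> pd.DataFrame:
    """Absolute prevalence difference on comorbidity diagnosis, per PRS decile.

    For each PRS bin, the prevalence of the index disease is computed in the
    arms with and without the comorbidity; the difference is reported in
    percentage points with Wilson CIs per arm. The summary attribute
    ``ratio_top_vs_bottom`` is the top-bin difference divided by the
    bottom-bin difference (NaN when either bin is flagged degenerate).
    """
    if cohort.comorbidity_flags is None or comorbidity_name not in cohort.comorbidity_flags:
        raise KeyError(f"no comorbidity flags for {comorbidity_name!r}")
    ph = cohort.phenotypes.set_index("id")
    bins = assignment.bins.reindex(ph.index)
    if bins.isna().any():
        raise ValueError("quantile assignment does not cover the cohort")
    com = cohort.comorbidity_flags[comorbidity_name].reindex(ph.index).astype(bool)
    case = ph["endo_case"].astype(bool)

    rows = []
    for b in range(1, assignment.k + 1):
        in_bin = bins == b
        w, wo = in_bin & com, in_bin & ~com
        n_w, n_wo = int(w.sum()), int(wo.sum())
        row = {"bin": b, "n_with": n_w, "n_without": n_wo, "flagged": n_w == 0 or n_wo == 0}
        if row["flagged"]:
            row.update(
                prevalence_with=np.nan, prevalence_without=np.nan, difference_pp=np.nan,
                ci_low_with=np.nan, ci_high_with=np.nan,
                ci_low_without=np.nan, ci_high_without=np.nan,
            )
        else:
            pw = case[w].mean()
            pwo = case[wo].mean()
            ciw = _wilson_ci(int(case[w].sum()), n_w)
            ciwo = _wilson_ci(int(case[wo].sum()), n_wo)
            row.update(
                prevalence_with=pw,
                prevalence_without=pwo,
                difference_pp=100.0 * (pw - pwo),
                ci_low_with=ciw[0], ci_high_with=ciw[1],
                ci_low_without=ciwo[0], ci_high_without=ciwo[1],
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("bin")
    bottom, top = table.loc[1], table.loc[assignment.k]
    if bottom["flagged"] or top["flagged"] or bottom["difference_pp"] == 0:
        table.attrs["ratio_top_vs_bottom"] = np.nan
    else:
        table.attrs["ratio_top_vs_bottom"] = float(
            top["difference_pp"] / bottom["difference_pp"]
        )
    return table


def decile_difference_ratio(d1_pp: float, d10_pp: float, ndigits: int = 1) -> float:
    """Top-versus-bottom-decile ratio of absolute prevalence differences.

    Rounded to one decimal place by default, the convention used when the
    ratio is quoted as a multiple (e.g. "2.7 times greater").
    """
    if d1_pp == 0:
        raise ZeroDivisionError("bottom-decile difference is zero")
    return round(d10_pp / d1_pp, ndigits)


def welch_t(a, b) -> tuple[float, float, float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns (t, df, p, mean_a, mean_b).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    na, nb = len(x), len(y)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0, float(x.mean()), float(y.mean())
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), float(x.mean()), float(y.mean())
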