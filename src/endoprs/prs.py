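"""Polygenic score scoring, standardization, stratification and summaries.

Scoring follows the plink ``--score`` average-per-allele convention: the
raw score is the mean over SNPs of weight x dosage / 2, with missing
dosages imputed to twice the effect-allele frequency when frequencies are
available and dropped (divisor adjusted) otherwise. Scores are z-scored
over the combined case-control analysis cohort, stratified into deciles or
centiles by rank, and summarized as per-bin odds ratios against a reference
bin (the median bin by default) with Woolf log-OR confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Cohort

__all__ = [
    "ScoringError",
    "score_genotypes",
    "standardize_scores",
    "QuantileAssignment",
    "assign_quantiles",
    "or_by_quantile",
    "roc_auc",
    "prevalence_by_burden",
]


class ScoringError(ValueError):
    pass


def score_genotypes(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Average-per-allele polygenic score for each row of ``dosages``.

    ``dosages`` is indexed by participant id with one column per snp_id and
    values in [0, 2] (NaN for missing). ``weights`` must have columns
    ``snp_id`` and ``weight``, optionally ``freq`` for mean imputation of
    missing dosages. Every weight-table SNP must be a dosage column.
    """
    snp_ids = weights["snp_id"].tolist()
    if len(set(snp_ids)) != len(snp_ids):
        raise ScoringError("duplicate snp_ids in weight table")
    missing = [s for s in snp_ids if s not in dosages.columns]
    if missing:
        raise ScoringError(f"SNPs absent from dosage matrix: {missing}")

    w = weights.set_index("snp_id")["weight"].reindex(snp_ids).to_numpy(dtype=float)
    mat = dosages[snp_ids].to_numpy(dtype=float)
    nan_mask = np.isnan(mat)
    n_snps = len(snp_ids)

    if nan_mask.any():
        if "freq" in weights.columns and weights["freq"].notna().all():
            freqs = weights.set_index("snp_id")["freq"].reindex(snp_ids).to_numpy(dtype=float)
            mat = np.where(nan_mask, 2.0 * freqs[None, :], mat)
            denom = np.full(len(mat), 2.0 * n_snps)
        else:
            mat = np.where(nan_mask, 0.0, mat)
            denom = 2.0 * (n_snps - nan_mask.sum(axis=1))
            if np.any(denom == 0):
                raise ScoringError("participant with no scored SNPs")
    else:
        denom = np.full(len(mat), 2.0 * n_snps)

    raw = (mat * w[None, :]).sum(axis=1) / denom
    return pd.Series(raw, index=dosages.index, name="raw_score")


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Z-score over the full scored set (sample SD, n-1 denominator)."""
    x = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ScoringError("non-finite scores")
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        raise ScoringError("zero score variance: cannot standardize")
    return pd.Series((x - x.mean()) / sd, index=scores.index, name="prs_z")


@dataclass
class QuantileAssignment:
    """Rank-based k-quantile bin membership (bins 1..k)."""

    bins: pd.Series  # id -> bin
    k: int
    bin_edges: np.ndarray  # score cut points, length k-1

    def ids_in_bin(self, b: int) -> pd.Index:
        return self.bins.index[self.bins == b]


def assign_quantiles(scores: pd.Series, k: int = 10) -> QuantileAssignment:
    """Assign each id to one of ``k`` equal-size bins by score rank.

    Ties are broken by stable input order, so bin sizes always differ by at
    most one; a warning is emitted if ties actually cross a bin boundary
    (the assignment is then order-dependent by contract).
    """
    n = len(scores)
    if n < k:
        raise ValueError(f"need at least k={k} scores, got {n}")
    x = scores.to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    bins = np.ceil(ranks * k / n).astype(int)

    sorted_x = x[order]
    edge_idx = np.ceil(np.arange(1, k) * n / k).astype(int) - 1
    edges = sorted_x[edge_idx]
    if np.any(sorted_x[np.minimum(edge_idx + 1, n - 1)] == edges):
        warnings.warn(
            "tied scores cross a quantile boundary; assignment uses stable input order",
            stacklevel=2,
        )
    return QuantileAssignment(
        bins=pd.Series(bins, index=scores.index, name="bin"), k=k, bin_edges=edges
    )


def or_by_quantile(
    assignment: QuantileAssignment,
    status: pd.Series,
    scores: pd.Series | None = None,
    reference_bin: int | None = None,
) -> pd.DataFrame:
    """Per-bin odds ratio of case status versus a reference bin.

    The reference defaults to the median bin (the 50th centile for k=100).
    Each bin's 2x2 against the reference yields an odds ratio with a Woolf
    (log-OR normal) 95% CI; the reference row has OR exactly 1 and a
    degenerate [1, 1] interval. ``scores`` (same index) adds a per-bin mean
    score column for plotting.
    """
    k = assignment.k
    ref = k // 2 if reference_bin is None else reference_bin
    status = status.reindex(assignment.bins.index).astype(bool)
    df = pd.DataFrame({"bin": assignment.bins, "case": status})
    tab = df.groupby("bin")["case"].agg(n_case="sum", n="count")
    tab["n_control"] = tab["n"] - tab["n_case"]
    if ref not in tab.index or tab.loc[ref, "n_case"] == 0 or tab.loc[ref, "n_control"] == 0:
        raise ValueError(f"reference bin {ref} lacks cases or controls")
    ra, rc = float(tab.loc[ref, "n_case"]), float(tab.loc[ref, "n_control"])

    rows = []
    for b, row in tab.iterrows():
        a, c = float(row["n_case"]), float(row["n_control"])
        if b == ref:
            orr, lo, hi = 1.0, 1.0, 1.0
        elif min(a, c) == 0 or min(ra, rc) == 0:
            orr, lo, hi = (np.inf if c == 0 else 0.0), np.nan, np.nan
        else:
            orr = (a * rc) / (c * ra)
            se = np.sqrt(1 / a + 1 / c + 1 / ra + 1 / rc)
            lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
        rows.append(
            {
                "bin": b,
                "n_case": int(row["n_case"]),
                "n_control": int(row["n_control"]),
                "odds_ratio": orr,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    out = pd.DataFrame(rows).set_index("bin")
    if scores is not None:
        out["mean_prs"] = scores.groupby(assignment.bins).mean()
    return out


def roc_auc(scores, status) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a random case outscores a random control,
    with ties counted half.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(x)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def prevalence_by_burden(
    cohort: Cohort,
    burden: pd.Series,
    cap: int | None = None,
) -> pd.DataFrame:
    """Endometriosis prevalence within groups of equal diagnosis count.

    ``burden`` maps participant id to a count (any metric from the burden
    table). Counts above ``cap``, if given, are pooled into a single top
    group labelled ``cap``. Groups with no members are omitted; prevalence
    carries a Wilson 95% binomial CI.
    """
    status = cohort.phenotypes.set_index("id")["endo_case"]
    b = burden.reindex(status.index)
    if b.isna().any():
        raise ValueError("burden does not cover all cohort ids")
    b = b.astype(int)
    if cap is not None:
        b = b.clip(upper=cap)
    df = pd.DataFrame({"count": b, "case": status.astype(bool)})
    grp = df.groupby("count")["case"].agg(n="count", n_case="sum")
    grp["prevalence"] = grp["n_case"] / grp["n"]
    lo, hi = [], []
    for _, row in grp.iterrows():
        ci = _wilson_ci(int(row["n_case"]), int(row["n"]))
        lo.append(ci[0])
        hi.append(ci[1])
    grp["ci_low"], grp["ci_high"] = lo, hi
    return grp.reset_index()


def _wilson_ci(x: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))
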