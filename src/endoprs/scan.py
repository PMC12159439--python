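"""Phenome-wide per-code association testing against case status.

Every distinct 4-character diagnosis code carried by at least one cohort
member is cross-tabulated against case status and tested with a Pearson
chi-squared test (no continuity correction), falling back to Fisher's exact
test whenever any expected cell count is below 5. Multiplicity is handled
with Benjamini-Hochberg FDR over all tested codes; the disease-associated
("comorbid") code set keeps significant codes with increased risk and then
applies chapter/code exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .icd import CHAPTER_LOOKUP, CodeSet, ExclusionRules
from .simulate import Cohort

__all__ = [
    "AssociationResult",
    "ScanResult",
    "test_code_association",
    "phenome_scan",
    "bh_fdr",
    "build_comorbid_set",
    "compare_code_sets",
    "compare_chapter_proportions",
]


@dataclass
class AssociationResult:
    """One code's 2x2 test against case status.

    ``table`` is (case_with, case_without, control_with, control_without);
    ``odds_ratio`` uses +inf/0 sentinels on zero cells and NaN for 0/0.
    """

    code: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    method: str  # "chi_squared" | "fisher"
    fdr_significant: bool = False
    p_adjusted: float = np.nan

    @property
    def direction(self) -> str:
        if np.isnan(self.odds_ratio) or self.odds_ratio == 1.0:
            return "undefined"
        return "increased" if self.odds_ratio > 1.0 else "decreased"


@dataclass
class ScanResult:
    cohort_label: str
    results: list[AssociationResult]
    q: float = 0.05

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return sum(r.fdr_significant for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            a, b, c, d = r.table
            rows.append(
                {
                    "code": r.code,
                    "n_case_with": a,
                    "n_case_without": b,
                    "n_control_with": c,
                    "n_control_without": d,
                    "or": r.odds_ratio,
                    "p": r.p_value,
                    "p_adj": r.p_adjusted,
                    "method": r.method,
                    "fdr_significant": r.fdr_significant,
                    "direction": r.direction,
                    "chapter": CHAPTER_LOOKUP.get(r.code[:3], -1),
                }
            )
        return pd.DataFrame(rows)


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    if b * c == 0:
        return np.nan if a * d == 0 else np.inf
    return (a * d) / (b * c)


def test_code_association(
    table: tuple[int, int, int, int]
) -> tuple[float, float, str]:
    """Test one 2x2 table (case_with, case_without, control_with, control_without).

    Returns (p_value, odds_ratio, method). Fisher's exact test (two-sided,
    point-probability method) is used iff any expected cell count is below
    5; otherwise Pearson chi-squared without continuity correction.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0:
        raise ValueError("degenerate table: empty case or control margin")
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if col1 == 0 or col2 == 0:
        # code in everyone or no one: no association information
        return 1.0, _odds_ratio(a, b, c, d), "chi_squared"
    expected_min = min(
        row1 * col1, row1 * col2, row2 * col1, row2 * col2
    ) / n
    orr = _odds_ratio(a, b, c, d)
    if expected_min < 5:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p), orr, "fisher"
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(p), orr, "chi_squared"


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _presence_counts(cohort: Cohort, resolution: int) -> pd.DataFrame:
    """Per-code binary-presence counts among cases and controls."""
    diag = cohort.diagnoses.copy()
    diag["code"] = diag["code"].str.slice(0, resolution)
    diag = diag.drop_duplicates(["id", "code"])
    status = cohort.phenotypes.set_index("id")["endo_case"]
    diag["endo_case"] = diag["id"].map(status).astype(bool)
    counts = (
        diag.groupby(["code", "endo_case"]).size().unstack(fill_value=0)
    )
    for col in (False, True):
        if col not in counts.columns:
            counts[col] = 0
    return counts.rename(columns={True: "case_with", False: "control_with"})


def phenome_scan(cohort: Cohort, resolution: int = 4, q: float = 0.05) -> ScanResult:
    """Test every observed code for association with case status.

    Per-person code presence is binary (a code counts once per person
    regardless of how many times it was recorded). Chi-squared p-values are
    computed vectorized; tables with any expected count below 5 are re-tested
    with Fisher's exact test. BH-FDR is applied at level ``q`` across all
    tested codes, before any chapter/code exclusion.
    """
    cohort.require_both_arms()
    counts = _presence_counts(cohort, resolution)
    n_case, n_control = cohort.n_cases, cohort.n_controls
    if counts.empty:
        return ScanResult(cohort.label, [], q=q)

    a = counts["case_with"].to_numpy(dtype=float)
    c = counts["control_with"].to_numpy(dtype=float)
    b = n_case - a
    d = n_control - c
    n = float(n_case + n_control)
    col1, col2 = a + c, b + d

    with np.errstate(divide="ignore", invalid="ignore"):
        expected_min = (
            np.minimum.reduce(
                [n_case * col1, n_case * col2, n_control * col1, n_control * col2]
            )
            / n
        )
        chi2 = n * (a * d - b * c) ** 2 / (n_case * n_control * col1 * col2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(col1 * col2 == 0, 1.0, p)
    method = np.where(expected_min < 5, "fisher", "chi_squared")

    for i in np.flatnonzero(method == "fisher"):
        p[i], _, _ = test_code_association(
            (int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        )

    reject, p_adj = bh_fdr(p, q=q)
    results = [
        AssociationResult(
            code=str(code),
            table=(int(a[i]), int(b[i]), int(c[i]), int(d[i])),
            odds_ratio=_odds_ratio(a[i], b[i], c[i], d[i]),
            p_value=float(p[i]),
            method=str(method[i]),
            fdr_significant=bool(reject[i]),
            p_adjusted=float(p_adj[i]),
        )
        for i, code in enumerate(counts.index)
    ]
    return ScanResult(cohort.label, results, q=q)


def build_comorbid_set(scan: ScanResult, rules: ExclusionRules | None = None) -> CodeSet:
    """Significant increased-risk codes, after chapter/code exclusions."""
    if rules is None:
        rules = ExclusionRules()
    kept = [
        r.code
        for r in scan.results
        if r.fdr_significant and r.direction == "increased" and rules.keeps(r.code)
    ]
    return CodeSet(frozenset(kept), resolution=4, label=f"comorbid[{scan.cohort_label}]")


def compare_code_sets(set_a: CodeSet, set_b: CodeSet) -> tuple[int, int, int]:
    """(n in both, n only in A, n only in B); sets must share a resolution."""
    if set_a.resolution != set_b.resolution:
        raise ValueError("code sets have different resolutions")
    both = set_a.codes & set_b.codes
    return len(both), len(set_a.codes - both), len(set_b.codes - both)


def compare_chapter_proportions(set_a: CodeSet, set_b: CodeSet) -> pd.DataFrame:
    """Per-chapter two-proportion tests between two code sets.

    For each chapter, tests whether the proportion of each set's codes
    falling in that chapter differs between the sets, using the chi-squared
    two-proportion test with Yates continuity correction (the R
    ``prop.test`` default). Chapters absent from both sets are reported with
    ``applicable=False``.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both code sets must be nonempty")
    na, nb = len(set_a), len(set_b)
    ca = pd.Series([CHAPTER_LOOKUP[c[:3]] for c in set_a]).value_counts()
    cb = pd.Series([CHAPTER_LOOKUP[c[:3]] for c in set_b]).value_counts()
    rows = []
    for ch in range(1, 23):
        xa, xb = int(ca.get(ch, 0)), int(cb.get(ch, 0))
        row = {
            "chapter": ch,
            "n_a": xa,
            "n_b": xb,
            "prop_a": xa / na,
            "prop_b": xb / nb,
            "applicable": xa + xb > 0,
            "p": np.nan,
        }
        if xa + xb > 0 and (na - xa) + (nb - xb) > 0:
            table = np.array([[xa, na - xa], [xb, nb - xb]])
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
            row["p"] = float(p)
        elif row["applicable"]:
            row["p"] = 1.0  # both sets entirely in this chapter
        rows.append(row)
    return pd.DataFrame(rows)
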