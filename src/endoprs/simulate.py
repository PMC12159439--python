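"""Synthetic case-control biobank cohorts under a liability-threshold model.

Disease liability is a standard-normal latent variable built from additive
components: a polygenic score ``g``, a latent shared factor ``C`` capturing
non-genetic risk shared with comorbid conditions, and independent noise.
An individual is a case when liability exceeds the standard-normal quantile
set by the disease prevalence. Each comorbidity has its own unit-variance
liability loading on the same ``g`` (pleiotropy, loading ``alpha``) and the
same ``C`` (shared environment, loading ``beta``), so the simulator can
generate cohorts in which comorbidities and the index disease co-occur
through genetic and/or non-genetic channels — the structure needed to study
index-event (collider) bias when analyses condition on case status.

Diagnosis streams are ICD-10-style: each diagnosed comorbidity contributes
its code, and a Poisson number of background codes per person is drawn from
per-chapter code pools that are independent of disease status by default.
All randomness flows from one root seed through named substreams, so adding
a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .icd import CHAPTER_LOOKUP, chapter_of, normalize_code

__all__ = [
    "ComorbiditySpec",
    "SimulationParams",
    "Participant",
    "Cohort",
    "DegenerateCohortError",
    "MatchingError",
    "default_index_comorbidities",
    "collider_default_params",
    "simulate_cohort",
    "simulate_genotypes",
    "age_match_controls",
]

# Substream tags: stable identifiers so every stage has its own RNG.
_STREAM_LIABILITY = 0
_STREAM_AGE = 1
_STREAM_BACKGROUND = 2
_STREAM_GENOTYPES = 3


class DegenerateCohortError(ValueError):
    """A realized cohort has an empty case or control arm."""


class MatchingError(ValueError):
    """Age matching failed for one or more cases."""

    def __init__(self, unmatched_ids: Sequence[str]):
        self.unmatched_ids = list(unmatched_ids)
        preview = ", ".join(self.unmatched_ids[:5])
        more = "" if len(self.unmatched_ids) <= 5 else f" (+{len(self.unmatched_ids) - 5} more)"
        super().__init__(f"no eligible controls for case ids: {preview}{more}")


@dataclass(frozen=True)
class ComorbiditySpec:
    """One comorbid condition's generative parameters.

    ``prs_loading`` (alpha) is the loading of the index-disease polygenic
    score on this condition's liability; ``shared_loading`` (beta) is the
    loading of the latent shared factor C. Residual variance must stay
    nonnegative: alpha^2 + beta^2 <= 1.
    """

    name: str
    icd_code: str
    prevalence: float
    prs_loading: float = 0.0
    shared_loading: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "icd_code", normalize_code(self.icd_code))
        if not 0 < self.prevalence < 1:
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")
        if self.prs_loading**2 + self.shared_loading**2 > 1 + 1e-12:
            raise ValueError(
                f"{self.name}: prs_loading^2 + shared_loading^2 > 1 "
                "(negative residual variance)"
            )


def default_index_comorbidities(
    prs_loading: float = 0.1, shared_loading: float = 0.5
) -> list[ComorbiditySpec]:
    """The six index comorbidities with biobank-scale female prevalences."""
    specs = [
        ("asthma", "J450", 0.12),
        ("diverticular_disease", "K579", 0.08),
        ("irritable_bowel_syndrome", "K589", 0.06),
        ("uterine_fibroids", "D259", 0.10),
        ("dysmenorrhea", "N946", 0.04),
        ("heavy_menstrual_bleeding", "N920", 0.10),
    ]
    return [
        ComorbiditySpec(n, c, p, prs_loading, shared_loading) for n, c, p in specs
    ]


# 20 distinct 3-character stems (none N80, none in excluded chapters) used by
# the documented collider-signature simulation.
_COLLIDER_CODES = [
    "D250", "E280", "F320", "G430", "I840", "J450", "K210", "K570", "K580",
    "L500", "M540", "M790", "N390", "N830", "N920", "N940", "N970", "O260",
    "R100", "R530",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one synthetic cohort.

    ``prs_r2`` is the proportion of index-disease liability variance
    explained by the polygenic score; ``shared_factor_loading_endo`` (b) is
    the loading of the latent shared factor C on the index-disease liability.
    ``background_rate`` is the mean number of background (status-independent)
    diagnosis codes per person; ``background_shared_coupling`` optionally
    couples the per-person background rate to C (log-linear, mean-preserving)
    to emulate healthcare-exposure confounding.
    """

    n_individuals: int = 200_000
    endo_prevalence: float = 0.05
    prs_r2: float = 0.26
    shared_factor_loading_endo: float = 0.45
    comorbidities: tuple[ComorbiditySpec, ...] = ()
    background_rate: float = 4.0
    background_shared_coupling: float = 0.0
    chapter_pool_sizes: Mapping[int, int] = field(
        default_factory=lambda: {ch: 10 for ch in range(1, 22)}
    )
    age_range: tuple[float, float] = (25.0, 70.0)
    control_case_ratio: int = 17
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "comorbidities", tuple(self.comorbidities))
        object.__setattr__(self, "chapter_pool_sizes", dict(self.chapter_pool_sizes))
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0 < self.endo_prevalence < 1:
            raise ValueError("endo_prevalence must be in (0,1)")
        if not 0 <= self.prs_r2 < 1:
            raise ValueError("prs_r2 must be in [0,1)")
        b = self.shared_factor_loading_endo
        if self.prs_r2 + b * b > 1 + 1e-12:
            raise ValueError(
                "prs_r2 + shared_factor_loading_endo^2 > 1 (negative residual variance)"
            )
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.background_rate > 0 and not any(
            v > 0 for v in self.chapter_pool_sizes.values()
        ):
            raise ValueError("background_rate > 0 requires a nonempty chapter pool")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be [min, max]")
        if self.control_case_ratio <= 0:
            raise ValueError("control_case_ratio must be positive")
        names = [c.name for c in self.comorbidities]
        if len(set(names)) != len(names):
            raise ValueError("comorbidity names must be unique")


def collider_default_params(seed: int = 0, n_individuals: int = 200_000) -> SimulationParams:
    """The documented default simulation for the index-event (collider) signature.

    Twenty comorbid conditions, each with a weak pleiotropic loading
    (alpha=0.1) and a strong shared-factor loading (beta=0.5) on liabilities
    whose shared factor also loads on the index disease (b=0.45), with the
    polygenic score explaining 26% of index-disease liability variance.
    """
    comorbidities = tuple(
        ComorbiditySpec(
            name=f"com_{code[:3]}", icd_code=code, prevalence=0.10,
            prs_loading=0.1, shared_loading=0.5,
        )
        for code in _COLLIDER_CODES
    )
    return SimulationParams(
        n_individuals=n_individuals,
        endo_prevalence=0.05,
        prs_r2=0.26,
        shared_factor_loading_endo=0.45,
        comorbidities=comorbidities,
        background_rate=4.0,
        seed=seed,
    )


@dataclass
class Participant:
    """One individual's phenotype, score and diagnosis stream."""

    id: str
    endo_case: bool
    age: float
    prs_z: float
    codes: list[str]
    comorbidity_flags: dict[str, bool] = field(default_factory=dict)


class Cohort:
    """A case-control cohort held as columnar tables.

    ``phenotypes``: one row per participant (columns ``id``, ``endo_case``,
    ``age``, ``prs_z``). ``diagnoses``: long format (``id``, ``code``),
    normalized dot-less codes. ``comorbidity_flags``: optional wide boolean
    table indexed by id, one column per named comorbidity.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        diagnoses: pd.DataFrame,
        comorbidity_flags: pd.DataFrame | None = None,
        label: str = "",
        provenance: object = None,
    ):
        phenotypes = phenotypes.reset_index(drop=True)
        if phenotypes["id"].duplicated().any():
            dup = phenotypes.loc[phenotypes["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate participant id: {dup!r}")
        self.phenotypes = phenotypes
        self.diagnoses = diagnoses.reset_index(drop=True)
        self.comorbidity_flags = comorbidity_flags
        self.label = label
        self.provenance = provenance

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> pd.Series:
        return self.phenotypes["id"]

    @property
    def status(self) -> np.ndarray:
        return self.phenotypes["endo_case"].to_numpy(dtype=bool)

    @property
    def prs_z(self) -> np.ndarray:
        return self.phenotypes["prs_z"].to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.status).sum())

    def __len__(self) -> int:
        return len(self.phenotypes)

    def require_both_arms(self) -> None:
        if self.n_cases == 0:
            raise DegenerateCohortError(f"cohort {self.label!r} has zero cases")
        if self.n_controls == 0:
            raise DegenerateCohortError(f"cohort {self.label!r} has zero controls")

    def participants(self) -> list[Participant]:
        """Materialize row-wise participant records (small cohorts / tests)."""
        codes = self.diagnoses.groupby("id")["code"].agg(list)
        flags = self.comorbidity_flags
        out = []
        for row in self.phenotypes.itertuples(index=False):
            out.append(
                Participant(
                    id=row.id,
                    endo_case=bool(row.endo_case),
                    age=float(row.age),
                    prs_z=float(row.prs_z),
                    codes=list(codes.get(row.id, [])),
                    comorbidity_flags={} if flags is None else {
                        k: bool(v) for k, v in flags.loc[row.id].items()
                    },
                )
            )
        return out


def _background_pool(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-chapter background code pools.

    Returns (codes, weights): 4-character codes built by cycling each
    chapter's valid 3-character prefixes with a trailing digit, skipping the
    endometriosis stem and any configured comorbidity codes; weights are
    uniform within the pooled codes so draw probability is proportional to
    pool size per chapter.
    """
    reserved = {c.icd_code for c in params.comorbidities}
    by_chapter: dict[int, list[str]] = {}
    for prefix, ch in CHAPTER_LOOKUP.items():
        by_chapter.setdefault(ch, []).append(prefix)
    codes: list[str] = []
    for ch, size in sorted(params.chapter_pool_sizes.items()):
        prefixes = sorted(by_chapter.get(ch, []))
        made = 0
        for k in range(size * 10):  # at most 10 subcodes per stem
            cand = prefixes[k % len(prefixes)] + str(k // len(prefixes))
            if cand[:3] == "N80" or cand in reserved:
                continue
            codes.append(cand)
            made += 1
            if made == size:
                break
    arr = np.asarray(codes, dtype=object)
    return arr, np.full(len(arr), 1.0 / max(len(arr), 1))


def simulate_cohort(
    params: SimulationParams,
    genotypes: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    label: str = "sim",
) -> Cohort:
    """Draw one cohort under the liability-threshold model.

    Each individual draws a polygenic score ``g ~ N(0,1)``, a latent shared
    factor ``C ~ N(0,1)`` and independent noise; index-disease liability is
    ``sqrt(prs_r2)*g + b*C + sqrt(1 - prs_r2 - b^2)*e`` and a participant is
    a case iff liability exceeds the quantile implied by the prevalence.
    Comorbidity liabilities are built the same way from their own loadings;
    diagnosed comorbidities append their ICD code to the participant's
    stream, followed by a Poisson number of background codes.

    If ``genotypes`` (a dosage matrix and weight table from
    :func:`simulate_genotypes`) is supplied, ``g`` is the standardized
    weighted dosage score instead of a direct normal draw, so file-based
    scoring can be exercised end to end.

    Deterministic given ``params.seed``.
    """
    n = params.n_individuals
    rng = np.random.default_rng([params.seed, _STREAM_LIABILITY])
    ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    if genotypes is None:
        g = rng.standard_normal(n)
    else:
        from .prs import score_genotypes, standardize_scores

        dosages, weights = genotypes
        if len(dosages) != n:
            raise ValueError("genotype matrix rows must equal n_individuals")
        raw = score_genotypes(dosages, weights)
        g = standardize_scores(raw).to_numpy(dtype=float)
        rng.standard_normal(n)  # keep downstream draws aligned with the default path

    C = rng.standard_normal(n)
    b = params.shared_factor_loading_endo
    resid = np.sqrt(max(1.0 - params.prs_r2 - b * b, 0.0))
    liability = np.sqrt(params.prs_r2) * g + b * C + resid * rng.standard_normal(n)
    threshold = stats.norm.ppf(1.0 - params.endo_prevalence)
    case = liability > threshold

    flags = {}
    for spec in params.comorbidities:
        res_j = np.sqrt(max(1.0 - spec.prs_loading**2 - spec.shared_loading**2, 0.0))
        lj = spec.prs_loading * g + spec.shared_loading * C + res_j * rng.standard_normal(n)
        flags[spec.name] = lj > stats.norm.ppf(1.0 - spec.prevalence)

    age_rng = np.random.default_rng([params.seed, _STREAM_AGE])
    ages = age_rng.uniform(params.age_range[0], params.age_range[1], n)

    # diagnosis streams: comorbidity codes then background codes
    rows_id: list[np.ndarray] = []
    rows_code: list[np.ndarray] = []
    for spec in params.comorbidities:
        mask = flags[spec.name]
        rows_id.append(ids[mask])
        rows_code.append(np.full(int(mask.sum()), spec.icd_code, dtype=object))

    if params.background_rate > 0:
        bg_rng = np.random.default_rng([params.seed, _STREAM_BACKGROUND])
        rate = np.full(n, params.background_rate)
        gamma = params.background_shared_coupling
        if gamma != 0.0:
            rate = params.background_rate * np.exp(gamma * C - gamma * gamma / 2.0)
        counts = bg_rng.poisson(rate)
        pool, _ = _background_pool(params)
        draws = bg_rng.integers(0, len(pool), int(counts.sum()))
        rows_id.append(np.repeat(ids, counts))
        rows_code.append(pool[draws])

    diagnoses = pd.DataFrame(
        {
            "id": np.concatenate(rows_id) if rows_id else np.array([], dtype=object),
            "code": np.concatenate(rows_code) if rows_code else np.array([], dtype=object),
        }
    )
    # per-person duplicates (comorbidity code also drawn as background) are
    # harmless: presence is binary everywhere downstream
    phenotypes = pd.DataFrame(
        {"id": ids, "endo_case": case, "age": ages, "prs_z": g}
    )
    flag_df = (
        pd.DataFrame(flags, index=pd.Index(ids, name="id")) if flags else None
    )
    cohort = Cohort(phenotypes, diagnoses, flag_df, label=label, provenance=params)
    cohort.require_both_arms()
    return cohort


def simulate_genotypes(
    params: SimulationParams, n_snps: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a dosage matrix and matching weight table.

    Per-SNP effect-allele frequencies are uniform on (0.05, 0.5), dosages
    binomial(2, freq), weights standard normal. The standardized weighted
    dosage sum is the polygenic score ``g`` when the matrix is passed back
    to :func:`simulate_cohort`, so the score's liability-variance share is
    exactly ``prs_r2`` by construction.

    Returns
    -------
    (dosages, weight_table)
        ``dosages``: DataFrame indexed by participant id, one column per
        snp_id, values in {0,1,2}. ``weight_table``: columns ``snp_id``,
        ``effect_allele``, ``weight``, ``freq``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng([params.seed, _STREAM_GENOTYPES])
    n = params.n_individuals
    ids = [f"P{i:07d}" for i in range(n)]
    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    freqs = rng.uniform(0.05, 0.5, n_snps)
    dosages = rng.binomial(2, freqs, size=(n, n_snps))
    weights = rng.standard_normal(n_snps)
    alleles = rng.choice(np.array(["A", "C", "G", "T"]), n_snps)
    dosage_df = pd.DataFrame(dosages, index=pd.Index(ids, name="id"), columns=snp_ids)
    weight_df = pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": alleles, "weight": weights, "freq": freqs}
    )
    return dosage_df, weight_df


def _next_free(parent: np.ndarray, i: int) -> int:
    """Path-compressed 'next unused index >= i' lookup."""
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        parent[i], i = root, parent[i]
    return root


def age_match_controls(
    cases: Cohort | pd.DataFrame,
    pool: Cohort | pd.DataFrame,
    ratio: int = 17,
    tolerance_years: float = 1.0,
    label: str = "matched",
) -> tuple[Cohort, pd.Series]:
    """Greedy without-replacement age matching of controls to cases.

    For each case (in id order), selects up to ``ratio`` unused controls
    whose age differs by at most ``tolerance_years``. Raises
    :class:`MatchingError` listing the case ids for which no eligible
    control exists.

    Accepts either Cohorts or bare phenotype frames; the pool must contain
    only non-cases. Returns the assembled case-control cohort and a Series
    of per-case match counts.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    case_ph = cases.phenotypes if isinstance(cases, Cohort) else cases
    pool_ph = pool.phenotypes if isinstance(pool, Cohort) else pool
    if bool(pool_ph["endo_case"].any()):
        raise ValueError("control pool contains cases")
    if not bool(case_ph["endo_case"].all()):
        raise ValueError("case table contains non-cases")

    pool_sorted = pool_ph.sort_values("age", kind="stable").reset_index(drop=True)
    pool_ages = pool_sorted["age"].to_numpy(dtype=float)
    npool = len(pool_sorted)
    parent = np.arange(npool + 1)  # sentinel npool == exhausted

    chosen: list[int] = []
    counts: dict[str, int] = {}
    unmatched: list[str] = []
    # process cases in age order, taking the youngest available control in
    # each window: the standard greedy that maximizes total matches
    for row in case_ph.sort_values("age", kind="stable").itertuples(index=False):
        lo = int(np.searchsorted(pool_ages, row.age - tolerance_years, side="left"))
        hi = int(np.searchsorted(pool_ages, row.age + tolerance_years, side="right"))
        if lo >= hi:
            unmatched.append(row.id)
            continue
        # a case is unmatched only if the pool has no member in its window;
        # windows emptied by earlier cases yield zero matches without error
        taken = 0
        i = _next_free(parent, lo)
        while i < hi and taken < ratio:
            chosen.append(i)
            parent[i] = i + 1
            taken += 1
            i = _next_free(parent, i + 1)
        counts[row.id] = taken
    if unmatched:
        raise MatchingError(unmatched)

    matched_controls = pool_sorted.iloc[sorted(chosen)]
    phenotypes = pd.concat([case_ph, matched_controls], ignore_index=True)
    keep_ids = set(phenotypes["id"])

    def _subset_diag(obj):
        if isinstance(obj, Cohort):
            return obj.diagnoses[obj.diagnoses["id"].isin(keep_ids)]
        return pd.DataFrame({"id": [], "code": []})

    diagnoses = pd.concat(
        [_subset_diag(cases), _subset_diag(pool)], ignore_index=True
    )
    flag_frames = [
        o.comorbidity_flags.loc[o.comorbidity_flags.index.isin(keep_ids)]
        for o in (cases, pool)
        if isinstance(o, Cohort) and o.comorbidity_flags is not None
    ]
    flags = pd.concat(flag_frames) if flag_frames else None
    cohort = Cohort(phenotypes, diagnoses, flags, label=label, provenance="age_match")
    return cohort, pd.Series(counts, name="n_matched")
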