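"""End-to-end orchestration of the two-cohort analysis.

The pipeline simulates (or loads) two cohorts, scans each for
disease-associated codes, and then applies the cross-cohort contract: the
comorbid code set discovered in cohort A is the one used to count comorbid
burden in cohort B and vice versa, so that per-person burden metrics are
never computed against a code set discovered in the same individuals
(same-cohort counting requires an explicit override). Downstream stages —
PRS stratification, prevalence-by-burden, the burden x PRS x status linear
interaction (overall, chapter-wise and leave-one-chapter-out), and the
multiplicative and additive PRS x comorbidity interactions — run per
cohort and write plain TSVs plus a JSON run manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .icd import ExclusionRules, burden_table
from .interactions import (
    additive_interaction,
    burden_prs_interaction,
    interaction_scan_by_chapter,
    multiplicative_interaction,
    welch_t,
)
from .io import write_cohort, write_code_set
from .prs import assign_quantiles, or_by_quantile, prevalence_by_burden, roc_auc
from .scan import build_comorbid_set, phenome_scan
from .simulate import Cohort, SimulationParams, default_index_comorbidities, simulate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_all", "CrossCohortError"]


class CrossCohortError(ValueError):
    """Raised when burden would be counted against a same-cohort code set."""


@dataclass
class PipelineConfig:
    params_a: SimulationParams
    params_b: SimulationParams
    q: float = 0.05
    rules: ExclusionRules = field(default_factory=ExclusionRules)
    out_dir: str = "endoprs_out"
    centile_k: int = 100
    allow_same_cohort: bool = False

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0,1)")
        if self.params_a.seed == self.params_b.seed:
            raise ValueError("cohorts A and B must use distinct seeds")

    @classmethod
    def default(cls, seed: int = 0, n_individuals: int = 20_000, **kw) -> "PipelineConfig":
        base = dict(
            n_individuals=n_individuals,
            comorbidities=tuple(default_index_comorbidities()),
        )
        return cls(
            params_a=SimulationParams(seed=seed * 2 + 1, **base),
            params_b=SimulationParams(seed=seed * 2 + 2, **base),
            **kw,
        )


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    version: str
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # relative path -> sha256
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_config(config: PipelineConfig) -> str:
    # hash only the scientific configuration, not the output location
    payload = repr((config.params_a, config.params_b, config.q, config.rules,
                    config.centile_k, config.allow_same_cohort))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cross_cohort_burden(
    cohort: Cohort, other_scan_set, rules: ExclusionRules, allow_same_cohort: bool = False
) -> pd.DataFrame:
    """Burden table for ``cohort`` using the OTHER cohort's comorbid set."""
    set_label = getattr(other_scan_set, "label", "")
    if not allow_same_cohort and cohort.label and cohort.label in set_label.replace(
        "comorbid[", ""
    ).rstrip("]").split(","):
        raise CrossCohortError(
            f"comorbid set {set_label!r} was discovered in cohort {cohort.label!r}; "
            "counting burden against a same-cohort set requires allow_same_cohort=True"
        )
    return burden_table(cohort.diagnoses, cohort.ids, other_scan_set, rules)


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, root: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    manifest.outputs[str(path.relative_to(root))] = _sha256(path)


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage for cohorts A and B; returns the run manifest."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(config),
        seeds={"A": config.params_a.seed, "B": config.params_b.seed},
        version=__version__,
    )

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.stage_seconds[stage] = round(time.perf_counter() - self.t0, 3)

        return _T()

    try:
        with timed("simulate"):
            cohorts = {
                "A": simulate_cohort(config.params_a, label="A"),
                "B": simulate_cohort(config.params_b, label="B"),
            }
            for lab, cohort in cohorts.items():
                for name, p in write_cohort(cohort, root / lab).items():
                    manifest.outputs[str(p.relative_to(root))] = _sha256(p)

        with timed("scan"):
            scans = {lab: phenome_scan(c, q=config.q) for lab, c in cohorts.items()}
            sets = {lab: build_comorbid_set(s, config.rules) for lab, s in scans.items()}
            for lab in cohorts:
                _write(scans[lab].to_frame(), root / lab / "scan.tsv", manifest, root, index=False)
                p = write_code_set(sets[lab], root / lab / "comorbid_set.tsv")
                manifest.outputs[str(p.relative_to(root))] = _sha256(p)
                if len(sets[lab]) == 0:
                    manifest.warnings.append(
                        f"cohort {lab}: empty comorbid set; comorbid burden metrics are all zero"
                    )

        with timed("burden"):
            other = {"A": "B", "B": "A"}
            burdens = {
                lab: cross_cohort_burden(
                    cohorts[lab], sets[other[lab]], config.rules, config.allow_same_cohort
                )
                for lab in cohorts
            }
            for lab in cohorts:
                _write(burdens[lab], root / lab / "burden.tsv", manifest, root)

        with timed("prs"):
            for lab, cohort in cohorts.items():
                # centiles need cases in every bin; fall back to deciles when sparse
                k = config.centile_k if cohort.n_cases >= 5 * config.centile_k else 10
                assignment = assign_quantiles(
                    cohort.phenotypes.set_index("id")["prs_z"], k=k
                )
                ors = or_by_quantile(
                    assignment,
                    cohort.phenotypes.set_index("id")["endo_case"],
                    scores=cohort.phenotypes.set_index("id")["prs_z"],
                )
                _write(ors, root / lab / f"or_by_{k}quantile.tsv", manifest, root)
                auc = roc_auc(cohort.prs_z, cohort.status)
                prev = {
                    m: prevalence_by_burden(cohort, burdens[lab][f"{m}_3char"], cap=20)
                    for m in ("total", "comorbid")
                }
                for m, tab in prev.items():
                    _write(tab, root / lab / f"prevalence_by_{m}_burden.tsv", manifest, root, index=False)
                case_b = burdens[lab].loc[cohort.ids[cohort.status]]
                ctrl_b = burdens[lab].loc[cohort.ids[~cohort.status]]
                t, df_, p, mean_case, mean_ctrl = welch_t(
                    case_b["total_3char"], ctrl_b["total_3char"]
                )
                summary = pd.DataFrame(
                    [
                        {"quantity": "auc", "value": auc},
                        {"quantity": "burden_t", "value": t},
                        {"quantity": "burden_t_p", "value": p},
                        {"quantity": "case_mean_total_3char", "value": mean_case},
                        {"quantity": "control_mean_total_3char", "value": mean_ctrl},
                    ]
                )
                _write(summary, root / lab / "summary.tsv", manifest, root, index=False)

        with timed("interact"):
            for lab, cohort in cohorts.items():
                fit = burden_prs_interaction(cohort, burdens[lab], metric="comorbid")
                _write(fit.to_frame(), root / lab / "interaction_comorbid.tsv", manifest, root, index=False)
                fit_t = burden_prs_interaction(cohort, burdens[lab], metric="total")
                _write(fit_t.to_frame(), root / lab / "interaction_total.tsv", manifest, root, index=False)
                chap = interaction_scan_by_chapter(cohort, burdens[lab], metric="comorbid")
                _write(chap, root / lab / "interaction_by_chapter.tsv", manifest, root, index=False)

                deciles = assign_quantiles(cohort.phenotypes.set_index("id")["prs_z"], k=10)
                add_rows, mult_rows = [], []
                if cohort.comorbidity_flags is not None:
                    for name in cohort.comorbidity_flags.columns:
                        tab = additive_interaction(cohort, name, deciles)
                        tab = tab.assign(comorbidity=name)
                        tab["ratio_top_vs_bottom"] = tab.attrs["ratio_top_vs_bottom"]
                        add_rows.append(tab.reset_index())
                        mfit = multiplicative_interaction(cohort, name)
                        frame = mfit.to_frame().assign(
                            comorbidity=name, converged=mfit.converged
                        )
                        mult_rows.append(frame)
                if add_rows:
                    _write(pd.concat(add_rows, ignore_index=True), root / lab / "additive_interaction.tsv", manifest, root, index=False)
                    _write(pd.concat(mult_rows, ignore_index=True), root / lab / "multiplicative_interaction.tsv", manifest, root, index=False)
    except Exception as exc:  # abort with stage context + partial manifest
        manifest.warnings.append(f"aborted: {type(exc).__name__}: {exc}")
        (root / "manifest.json").write_text(manifest.to_json())
        raise

    (root / "manifest.json").write_text(manifest.to_json())
    return manifest
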