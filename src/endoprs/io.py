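"""Plain-TSV readers and writers for cohorts, code sets and score tables.

Schemas
-------
phenotypes.tsv : ``id``, ``endo_case`` (0/1), ``age``, optional ``prs_z``
diagnoses.tsv  : ``id``, ``code`` (dot-less ICD-10-style; dotted inputs are
                 normalized on load and the fix-ups are logged)
weights.tsv    : ``snp_id``, ``effect_allele``, ``weight``, optional ``freq``
dosages.tsv    : ``id`` plus one column per snp_id, values in [0, 2]
codeset.tsv    : ``code``, ``chapter``, ``label``
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .icd import CodeSet, chapter_of, normalize_code
from .simulate import Cohort, ComorbiditySpec, SimulationParams

logger = logging.getLogger("endoprs")

__all__ = [
    "SchemaError",
    "load_cohort",
    "write_cohort",
    "load_weight_table",
    "load_dosages",
    "load_code_set",
    "write_code_set",
    "params_from_dict",
    "load_config_yaml",
]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_cohort(
    phenotype_path, diagnosis_path, score_path=None, label: str = ""
) -> Cohort:
    """Load a cohort from phenotype + long-diagnosis TSVs.

    Diagnosis ids must be a subset of phenotype ids; dotted codes are
    normalized silently (logged). An optional score TSV (``id``, ``prs_z``)
    overrides/provides the score column.
    """
    ph = pd.read_csv(phenotype_path, sep="\t", dtype={"id": str})
    _require_columns(ph, ["id", "endo_case", "age"], phenotype_path)
    ph["endo_case"] = ph["endo_case"].astype(int).astype(bool)
    if "prs_z" not in ph.columns:
        ph["prs_z"] = float("nan")

    diag = pd.read_csv(diagnosis_path, sep="\t", dtype=str)
    _require_columns(diag, ["id", "code"], diagnosis_path)
    normalized = diag["code"].map(normalize_code)
    n_fixed = int((normalized != diag["code"]).sum())
    if n_fixed:
        logger.info("normalized %d diagnosis codes (dots/case) in %s", n_fixed, diagnosis_path)
    diag["code"] = normalized

    unknown = set(diag["id"]) - set(ph["id"])
    if unknown:
        raise SchemaError(
            f"{diagnosis_path}: {len(unknown)} diagnosis ids absent from phenotype table"
        )
    if score_path is not None:
        sc = pd.read_csv(score_path, sep="\t", dtype={"id": str})
        _require_columns(sc, ["id", "prs_z"], score_path)
        ph = ph.drop(columns=["prs_z"]).merge(sc[["id", "prs_z"]], on="id", how="left")
        if ph["prs_z"].isna().any():
            n = int(ph["prs_z"].isna().sum())
            raise SchemaError(f"{score_path}: {n} phenotype ids lack a score")
    logger.info(
        "loaded cohort %s: %d participants, %d diagnosis rows", label, len(ph), len(diag)
    )
    return Cohort(ph, diag, label=label, provenance=str(phenotype_path))


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write phenotype/diagnosis (and flags) TSVs; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ph = cohort.phenotypes.copy()
    ph["endo_case"] = ph["endo_case"].astype(int)
    paths["phenotypes"] = out / "phenotypes.tsv"
    ph.to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["diagnoses"] = out / "diagnoses.tsv"
    cohort.diagnoses.to_csv(paths["diagnoses"], sep="\t", index=False)
    if cohort.comorbidity_flags is not None:
        paths["comorbidity_flags"] = out / "comorbidity_flags.tsv"
        cohort.comorbidity_flags.astype(int).to_csv(paths["comorbidity_flags"], sep="\t")
    return paths


def load_weight_table(path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "effect_allele": str})
    _require_columns(w, ["snp_id", "effect_allele", "weight"], path)
    if w["snp_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate snp_ids")
    return w


def load_dosages(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", dtype={"id": str})
    _require_columns(d, ["id"], path)
    return d.set_index("id")


def load_code_set(path, resolution: int = 4, label: str = "") -> CodeSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["code"], path)
    codes = frozenset(normalize_code(c) for c in df["code"])
    return CodeSet(codes, resolution=resolution, label=label or str(path))


def write_code_set(code_set: CodeSet, path) -> Path:
    path = Path(path)
    rows = [
        {"code": c, "chapter": chapter_of(c), "label": code_set.label}
        for c in sorted(code_set.codes)
    ]
    pd.DataFrame(rows, columns=["code", "chapter", "label"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def params_from_dict(d: dict) -> SimulationParams:
    """Build SimulationParams from a YAML-style mapping."""
    d = dict(d)
    comorbidities = tuple(
        ComorbiditySpec(**c) for c in d.pop("comorbidities", [])
    )
    pools = d.pop("chapter_pool_sizes", None)
    kwargs = dict(d, comorbidities=comorbidities)
    if pools is not None:
        kwargs["chapter_pool_sizes"] = {int(k): int(v) for k, v in pools.items()}
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    return SimulationParams(**kwargs)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
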