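import numpy as np
import pandas as pd
import pytest

from endoprs.icd import CodeSet
from endoprs.simulate import (
    Cohort,
    SimulationParams,
    default_index_comorbidities,
    simulate_cohort,
)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Six participants, hand-written diagnosis streams."""
    phenotypes = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(6)],
            "endo_case": [True, True, False, False, False, False],
            "age": [40.0, 45.0, 41.0, 44.0, 39.0, 50.0],
            "prs_z": [1.2, 0.3, -0.5, 0.1, -1.0, 0.4],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "id": ["p0", "p0", "p0", "p1", "p2", "p3", "p3"],
            "code": ["N801", "D259", "K579", "K580", "D259", "K579", "J459"],
        }
    )
    flags = pd.DataFrame(
        {"uterine_fibroids": [True, False, True, False, False, False]},
        index=pd.Index([f"p{i}" for i in range(6)], name="id"),
    )
    return Cohort(phenotypes, diagnoses, flags, label="tiny")


@pytest.fixture(scope="session")
def sim_cohort() -> Cohort:
    """A mid-size simulated cohort with the six index comorbidities."""
    params = SimulationParams(
        n_individuals=20_000,
        comorbidities=tuple(default_index_comorbidities()),
        background_rate=3.0,
        seed=42,
    )
    return simulate_cohort(params, label="sim20k")


@pytest.fixture(scope="session")
def big_artifact_cohort() -> Cohort:
    """Large cohort with shared-factor comorbidities and no background codes,
    used for the additive-vs-multiplicative scale comparisons."""
    params = SimulationParams(
        n_individuals=200_000,
        comorbidities=tuple(default_index_comorbidities()),
        background_rate=0.0,
        seed=3,
    )
    return simulate_cohort(params, label="artifact200k")


@pytest.fixture(scope="session")
def index_code_set(sim_cohort) -> CodeSet:
    specs = sim_cohort.provenance.comorbidities
    return CodeSet(frozenset(s.icd_code for s in specs), resolution=4, label="index")
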