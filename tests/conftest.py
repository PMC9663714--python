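"""Shared fixtures: small simulated populations and constructed histories."""

import numpy as np
import pandas as pd
import pytest

from glycorank.simulate import (
    PatientHistory,
    RegimenSpec,
    SimulationConfig,
    simulate_population,
)


def make_history(patient_id="P0", birth_day=-20000, sex="M", labs=None,
                 prescriptions=None, diagnoses=None, **demo_extra):
    """Hand-constructed patient history for enumerated-truth tests."""
    demo = {
        "patient_id": patient_id,
        "birth_day": birth_day,
        "sex": sex,
        "zcta_income": 55000.0,
        "zcta_frac_white": 0.6,
        "zcta_frac_black": 0.2,
        "zcta_frac_asian": 0.1,
        "zcta_frac_other": 0.1,
    }
    demo.update(demo_extra)
    return PatientHistory(
        patient_id=patient_id,
        demographics=demo,
        labs=pd.DataFrame(labs or [], columns=["day", "test_name", "value"]),
        prescriptions=pd.DataFrame(
            prescriptions or [], columns=["fill_day", "drug_class", "days_supply"]
        ),
        diagnoses=pd.DataFrame(diagnoses or [], columns=["day", "condition_category"]),
    )


def hba1c(day, value):
    return {"day": day, "test_name": "hba1c", "value": value}


def rx(fill_day, drug_class, days_supply):
    return {"fill_day": fill_day, "drug_class": drug_class,
            "days_supply": days_supply}


def dx(day, category):
    return {"day": day, "condition_category": category}


TWO_REGIMENS = (
    RegimenSpec(frozenset(["metformin"]), -0.9),
    RegimenSpec(frozenset(["metformin", "glp1"]), -1.7),
)

THREE_REGIMENS = (
    RegimenSpec(frozenset(["metformin"]), -0.9),
    RegimenSpec(frozenset(["metformin", "glp1"]), -1.7),
    RegimenSpec(frozenset(["metformin", "sglt2"]), -1.3),
)


@pytest.fixture(scope="session")
def small_population():
    """600 patients under default study conditions (one shared copy)."""
    cfg = SimulationConfig(n_patients=600, seed=11)
    histories, truth = simulate_population(cfg)
    return cfg, histories, truth


@pytest.fixture(scope="session")
def confounded_two_arm():
    """A confounded two-regimen population large enough for propensity work."""
    cfg = SimulationConfig(
        n_patients=4000,
        seed=17,
        confounding_strength=1.5,
        missingness_rates={},
        regimen_catalog=TWO_REGIMENS,
    )
    histories, truth = simulate_population(cfg)
    return cfg, histories, truth


@pytest.fixture(scope="session")
def confounded_two_arm_snapshots(confounded_two_arm):
    from glycorank.cohorts import apply_exclusions, build_snapshot_table

    cfg, histories, truth = confounded_two_arm
    snaps = build_snapshot_table(apply_exclusions(histories))
    return cfg, snaps, truth
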