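"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from persistkit import ClaimsBundle, SimulationConfig, generate_cohort


def make_claims(patient_id: str, claims: list[tuple[int, str]],
                setting: str = "outpatient") -> pd.DataFrame:
    """Drug-claim table from (day, biologic class) pairs for one patient."""
    return pd.DataFrame(
        [(patient_id, day, f"BT-{drug}", drug, setting) for day, drug in claims],
        columns=["patient_id", "date", "drug_code", "bt_class", "setting"],
    )


def make_unit(patient_id: str = "P1", drug: str = "ADL", index_day: int = 0,
              obs_start: int = 0, obs_end: int = 400, age: int = 50, sex: str = "M"):
    return SimpleNamespace(
        unit_id=f"{patient_id}:{drug}", patient_id=patient_id, drug=drug,
        index_day=index_day, obs_start=obs_start, obs_end=obs_end, age=age, sex=sex,
    )


def oracle_episode(index_day: int, own_days, other_days, obs_end: int,
                   interval: int, gap: int, switch_on_same_day: bool = True):
    """Brute-force day-by-day episode scan, independent of the implementation.

    Walks every calendar day from the index: tracks the most recent index-drug
    claim, proves a gap on the first day the claim-free span exceeds
    interval+gap (event backdated to last claim + interval), and fires a
    switch when another biologic is claimed while the gap is still unproven.
    Returns (status, end_day since index).
    """
    own = set(d for d in own_days if d >= index_day)
    others = set(d for d in other_days if d >= index_day)
    non_refill = interval + gap
    last_own = None
    for day in range(index_day, obs_end + 1):
        if last_own is not None and day - last_own > non_refill:
            return "gap_discontinued", last_own + interval - index_day
        if day in others:
            tie_own = day in own
            if not tie_own or switch_on_same_day:
                return "switch_discontinued", day - index_day
        if day in own:
            last_own = day
    return "censored", obs_end - index_day


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort under the default study conditions."""
    config = SimulationConfig(n_patients=300, seed=20260926)
    bundle, truth = generate_cohort(config)
    return config, bundle, truth


@pytest.fixture()
def tiny_bundle() -> ClaimsBundle:
    """Three hand-written patients exercising inclusion/exclusion paths."""
    enrollment = pd.DataFrame(
        [("A", 0, 800, 50, "F"), ("B", 0, 800, 40, "M"), ("C", 0, 800, 61, "M")],
        columns=["patient_id", "obs_start", "obs_end", "age", "sex"],
    )
    diagnoses = pd.DataFrame(
        [("A", 10, "L40.5"), ("B", 20, "L20.0"), ("C", 30, "L40"), ("C", 40, "M05.9")],
        columns=["patient_id", "date", "icd10"],
    )
    drug_claims = pd.concat(
        [make_claims("A", [(100, "UST"), (190, "UST")]),
         make_claims("C", [(120, "ADL")])],
        ignore_index=True,
    )
    costs = pd.DataFrame(
        [("A", 100, 500000.0, "OP", True), ("A", 90, 12000.0, "RX", False)],
        columns=["patient_id", "date", "amount_jpy", "category", "is_bt_drug_cost"],
    )
    return ClaimsBundle(enrollment, diagnoses, drug_claims, costs)
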