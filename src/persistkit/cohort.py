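"""Cohort construction: selection cascade, patient units, naive status.

The selection cascade mirrors the standard claims workflow: find patients
with both a psoriasis diagnosis (ICD-10 L40) and at least one biologic claim,
drop patients carrying a diagnosis of rheumatoid arthritis, inflammatory
bowel disease, ankylosing spondylitis or juvenile arthritis (biologics for
those indications would confound drug-survival attribution), then split each
remaining patient into one analysis unit per biologic received — multiple
biologic cycles in one patient are deliberately counted as separate units.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bundle import ClaimsBundle
from .config import DRUGS, CodePolicy

LOOKBACK_DAYS = 365  # naive look-back and pre-index cost window
FOLLOWUP_DAYS = 365  # post-index cost window

PATIENT_UNIT_COLUMNS = [
    "unit_id", "patient_id", "drug", "index_day",
    "obs_start", "obs_end", "age", "sex",
]


@dataclass
class CascadeLog:
    """Stage counts of the selection funnel, for a patient-flow report."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        self.stages.append((stage, int(count)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


def _match_any(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    hit = pd.Series(False, index=codes.index)
    for p in prefixes:
        hit |= codes.str.startswith(p)
    return hit


def select_psoriasis_bt_patients(
    bundle: ClaimsBundle, codes: CodePolicy, log: CascadeLog | None = None
) -> set[str]:
    """Patients with >=1 inclusion-code diagnosis and >=1 biologic claim."""
    dx = bundle.diagnoses
    inc = dx[_match_any(dx["icd10"], codes.inclusion_codes)] if len(dx) else dx
    dx_patients = set(inc["patient_id"])
    bt_patients = set(bundle.drug_claims["patient_id"])
    selected = dx_patients & bt_patients
    if log is not None:
        log.add("inclusion-code diagnosis claims", len(inc))
        log.add("patients with inclusion diagnosis", len(dx_patients))
        log.add("biologic claims", len(bundle.drug_claims))
        log.add("patients with biologic claims", len(bt_patients))
        log.add("patients with both", len(selected))
    return selected


def apply_exclusions(
    patients: set[str], bundle: ClaimsBundle, codes: CodePolicy, log: CascadeLog | None = None
) -> set[str]:
    """Drop any patient with an exclusion-code diagnosis at any time."""
    dx = bundle.diagnoses
    flagged = set(dx.loc[_match_any(dx["icd10"], codes.exclusion_codes), "patient_id"]) if len(dx) else set()
    kept = patients - flagged
    if log is not None:
        log.add("excluded for competing diagnoses", len(patients & flagged))
        log.add("patients after exclusions", len(kept))
    return kept


def build_patient_units(patients: set[str], bundle: ClaimsBundle) -> pd.DataFrame:
    """One analysis unit per (patient, biologic); index = first claim of that drug.

    Raises on drug claims whose ``bt_class`` is not a recognised biologic.
    """
    claims = bundle.drug_claims
    claims = claims[claims["patient_id"].isin(patients)]
    unknown = set(claims["bt_class"]) - set(DRUGS)
    if unknown:
        raise ValueError(f"unknown biologic class code(s): {sorted(unknown)}")
    enr = bundle.enrollment.set_index("patient_id")
    if not len(claims):
        return pd.DataFrame(columns=PATIENT_UNIT_COLUMNS)
    first = (
        claims.groupby(["patient_id", "bt_class"], as_index=False)["date"]
        .min()
        .rename(columns={"bt_class": "drug", "date": "index_day"})
    )
    first["unit_id"] = first["patient_id"] + ":" + first["drug"]
    for col in ("obs_start", "obs_end", "age", "sex"):
        first[col] = first["patient_id"].map(enr[col])
    units = first[PATIENT_UNIT_COLUMNS].sort_values("unit_id", ignore_index=True)
    return units


def classify_naive(
    units: pd.DataFrame, bundle: ClaimsBundle, unknown_is_naive: bool = False
) -> pd.Series:
    """Boolean naive flag per unit: no biologic claim of any class in the
    365 days before index.

    A unit whose pre-index enrollment is shorter than the look-back window
    cannot be proven naive; it is labelled experienced unless
    ``unknown_is_naive`` is set.
    """
    claims = bundle.drug_claims
    flags = []
    for row in units.itertuples(index=False):
        observable = row.index_day - row.obs_start >= LOOKBACK_DAYS
        if not observable and not unknown_is_naive:
            flags.append(False)
            continue
        window = claims[
            (claims["patient_id"] == row.patient_id)
            & (claims["date"] >= row.index_day - LOOKBACK_DAYS)
            & (claims["date"] <= row.index_day - 1)
        ]
        flags.append(len(window) == 0)
    return pd.Series(flags, index=units.index, name="naive")


def select_cost_population(units: pd.DataFrame) -> pd.DataFrame:
    """Units with a full 12-month window on both sides of the index date."""
    keep = (units["obs_start"] <= units["index_day"] - LOOKBACK_DAYS) & (
        units["obs_end"] >= units["index_day"] + FOLLOWUP_DAYS
    )
    return units[keep].reset_index(drop=True)


def comorbidity_flags(units: pd.DataFrame, bundle: ClaimsBundle, codes: CodePolicy) -> pd.DataFrame:
    """Per-unit boolean flag for each configured comorbidity (any-time diagnosis)."""
    dx = bundle.diagnoses
    out = {}
    for cond, prefixes in codes.comorbidity_code_map.items():
        flagged = set(dx.loc[_match_any(dx["icd10"], prefixes), "patient_id"]) if len(dx) else set()
        out[cond] = units["patient_id"].isin(flagged)
    return pd.DataFrame(out, index=units.index)
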