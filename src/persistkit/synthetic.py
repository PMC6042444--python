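"""Seeded synthetic claims generator with known ground truth.

Emulates an employer-insurance claims extract for psoriasis patients on
biologic therapy: one enrollment row per patient, psoriasis / exclusion /
comorbidity diagnoses, biologic drug claims on each drug's dosing schedule,
and monthly cost records by category.  Every simulated (patient, drug) unit
carries a ground-truth record (true discontinuation day, cause, 12-month
persistence) so downstream episode construction and survival estimation can
be verified against the generative model.

Timing model
------------
A patient's index drug is claimed at the index day and every
``dosing_interval_days`` thereafter.  After each administration the patient
continues to the next one with probability ``(1-h)**(interval/30)`` where
``h`` is the per-30-day discontinuation hazard, i.e. discontinuation is
geometric on a 30-day cycle grid.  The *true discontinuation day* is the day
of the last administration received; the corresponding refill-gap event time
is one dosing interval later.  A discontinuation is a *switch* with
probability ``switch_probability``, in which case the replacement biologic's
claims start one dosing interval after the last index-drug claim.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .config import DRUGS, SimulationConfig

#: ICD-10 codes emitted per simulated condition (one representative code each).
CONDITION_CODES = {
    "psoriasis": "L40.0",
    "rheumatoid_arthritis": "M05.9",
    "inflammatory_bowel_disease": "K50.9",
    "ankylosing_spondylitis": "M45",
    "juvenile_arthritis": "M08.0",
    "obesity": "E66.0",
    "diabetes_without_complication": "E11.9",
    "diabetes_with_complication": "E11.2",
    "hypertension": "I10",
    "hyperlipidemia": "E78.0",
    "old_myocardial_infarction": "I25.2",
    "heart_failure": "I50.9",
}

GROUND_TRUTH_COLUMNS = [
    "patient_id", "drug", "index_day", "disc_day", "cause", "persistent_12m", "role",
]


@dataclass
class GroundTruth:
    """One record per simulated (patient, drug) unit.

    ``disc_day`` is the absolute day of the last administration when the unit
    truly discontinues (pd.NA otherwise); ``cause`` is ``"stop"``,
    ``"switch"`` or ``"none"``; ``persistent_12m`` is True when the refill-gap
    event time (``disc_day + interval``) falls at or after day 365 post-index,
    or when no discontinuation occurs.  ``role`` distinguishes ``index``
    units (full geometric discontinuation model) from ``prior`` stubs (the
    single pre-index administration given to experienced patients) and
    ``switch`` destinations (replacement therapy, runs to end of observation).
    """

    units: pd.DataFrame

    def for_unit(self, patient_id: str, drug: str) -> pd.Series:
        match = self.units[(self.units.patient_id == patient_id) & (self.units.drug == drug)]
        if len(match) != 1:
            raise KeyError(f"expected exactly one ground-truth record for ({patient_id}, {drug})")
        return match.iloc[0]


def _gamma(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Positive skewed draw with the given mean; dispersion is var/mean^2."""
    if mean <= 0:
        return 0.0
    shape = 1.0 / dispersion
    return float(rng.gamma(shape, mean / shape))


def _drug_claim_schedule(
    rng: np.random.Generator, start: int, obs_end: int, interval: int, hazard: float
) -> tuple[list[int], int | None]:
    """Claim days from ``start`` until discontinuation or enrollment end.

    Returns (claim days, true discontinuation day or None).  The
    discontinuation day is the last claim received; None means the patient was
    still on schedule when observation ended.
    """
    p_stop = 1.0 - (1.0 - hazard) ** (interval / 30.0)
    days: list[int] = []
    day = start
    while day <= obs_end:
        days.append(day)
        if rng.random() < p_stop:
            return days, day
        day += interval
    return days, None


def sample_survival_times(
    rng: np.random.Generator, n: int, hazard: float, interval: int = 30, obs_days: int = 730
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (time, event) pairs from the generator's discontinuation model.

    The event time is the refill-gap convention ``last administration +
    interval``; units still on schedule at ``obs_days`` are censored there.
    Useful for calibration studies that need survival samples without a full
    claims bundle.
    """
    times = np.empty(n, dtype=float)
    events = np.empty(n, dtype=bool)
    for i in range(n):
        _, disc = _drug_claim_schedule(rng, 0, obs_days, interval, hazard)
        if disc is None:
            times[i], events[i] = obs_days, False
        else:
            times[i], events[i] = disc + interval, True
    return times, events


def generate_cohort(config: SimulationConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Simulate a claims bundle plus per-unit ground truth.

    Deterministic for a fixed config (the seed lives in the config): the same
    inputs yield identical tables.
    """
    rng = np.random.default_rng(config.seed)
    drugs = list(config.drug_mix)
    mix = np.array([config.drug_mix[d] for d in drugs])

    enr_rows, dx_rows, claim_rows, cost_rows, truth_rows = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        obs_start, obs_end = 0, config.enrollment_span_days
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 74))
        sex = "F" if rng.random() < config.female_fraction else "M"
        enr_rows.append((pid, obs_start, obs_end, age, sex))

        lo, hi = config.index_day_range
        index_day = int(rng.integers(lo, min(hi, obs_end) + 1))

        # diagnoses: psoriasis for (almost) all, exclusions and comorbidities at prevalence
        if rng.random() < config.l40_fraction:
            dx_rows.append((pid, int(rng.integers(obs_start, index_day + 1)), CONDITION_CODES["psoriasis"]))
        for cond, prev in {**config.exclusion_prevalence, **config.comorbidity_prevalence}.items():
            if rng.random() < prev:
                dx_rows.append((pid, int(rng.integers(obs_start, obs_end + 1)), CONDITION_CODES[cond]))

        index_drug = drugs[int(rng.choice(len(drugs), p=mix))]
        naive = rng.random() < config.naive_fraction
        prior_drug = None
        if not naive:
            others = [d for d in DRUGS if d != index_drug]
            prior_drug = others[int(rng.choice(len(others)))]
            prior_day = index_day - int(rng.integers(30, 301))
            if prior_day >= obs_start:
                claim_rows.append((pid, prior_day, f"BT-{prior_drug}", prior_drug, "outpatient"))
                # stub unit for the abandoned prior biologic: one administration, never persistent
                truth_rows.append((pid, prior_drug, prior_day, prior_day, "switch", False, "prior"))
            else:
                prior_drug = None

        interval = config.dosing_interval_days[index_drug]
        hazard = config.monthly_discontinuation_hazard[index_drug]
        days, disc_day = _drug_claim_schedule(rng, index_day, obs_end, interval, hazard)
        switch_drug = None
        cause = "none"
        if disc_day is not None:
            is_switch = rng.random() < config.switch_probability
            cause = "switch" if is_switch else "stop"
            if is_switch:
                candidates = [d for d in DRUGS if d not in (index_drug, prior_drug)]
                switch_drug = candidates[int(rng.choice(len(candidates)))]
        for day in days:
            setting = "inpatient" if rng.random() < config.inpatient_claim_fraction else "outpatient"
            claim_rows.append((pid, day, f"BT-{index_drug}", index_drug, setting))
            cost_rows.append((pid, day, round(_gamma(rng, config.bt_claim_cost_jpy[index_drug],
                                                     config.bt_cost_dispersion), 0),
                              "IP" if setting == "inpatient" else "OP", True))
        persistent = disc_day is None or (disc_day + interval - index_day) >= 365
        truth_rows.append((pid, index_drug, index_day,
                           disc_day if disc_day is not None else pd.NA, cause, persistent, "index"))

        if switch_drug is not None:
            switch_day = disc_day + interval
            if switch_day <= obs_end:
                sw_interval = config.dosing_interval_days[switch_drug]
                day = switch_day
                while day <= obs_end:  # replacement therapy runs to end of observation
                    setting = "inpatient" if rng.random() < config.inpatient_claim_fraction else "outpatient"
                    claim_rows.append((pid, day, f"BT-{switch_drug}", switch_drug, setting))
                    cost_rows.append((pid, day, round(_gamma(rng, config.bt_claim_cost_jpy[switch_drug],
                                                             config.bt_cost_dispersion), 0),
                                      "IP" if setting == "inpatient" else "OP", True))
                    day += sw_interval
                truth_rows.append((pid, switch_drug, switch_day, pd.NA, "none", True, "switch"))

        # monthly background (non-biologic) costs, anchored to the index day so the
        # 12-month pre and post windows each contain exactly 12 emissions
        month = index_day + 30 * int(np.ceil((obs_start - index_day) / 30))
        while month <= obs_end:
            params = config.pre_cost_params if month < index_day else config.post_cost_params
            for cat, (mean, disp) in params.items():
                amt = round(_gamma(rng, mean, disp), 0)
                if amt > 0:
                    cost_rows.append((pid, month, amt, cat, False))
            month += 30

    bundle = ClaimsBundle(
        enrollment=pd.DataFrame(enr_rows, columns=["patient_id", "obs_start", "obs_end", "age", "sex"]),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd10"]),
        drug_claims=pd.DataFrame(claim_rows, columns=["patient_id", "date", "drug_code", "bt_class", "setting"]),
        costs=pd.DataFrame(cost_rows, columns=["patient_id", "date", "amount_jpy", "category", "is_bt_drug_cost"]),
    )
    for name, df in bundle.tables().items():
        if not len(df):
            continue
        sort_cols = ["patient_id", "date"] if "date" in df.columns else ["patient_id"]
        df.sort_values(sort_cols, kind="stable", inplace=True, ignore_index=True)
    if len(bundle.costs):
        bundle.costs["amount_jpy"] = bundle.costs["amount_jpy"].astype(float)
        bundle.costs["is_bt_drug_cost"] = bundle.costs["is_bt_drug_cost"].astype(bool)

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    if len(truth):
        truth["disc_day"] = truth["disc_day"].astype("Int64")
        truth["persistent_12m"] = truth["persistent_12m"].astype(bool)
        truth.sort_values(["patient_id", "drug"], kind="stable", inplace=True, ignore_index=True)
    return bundle, GroundTruth(truth)
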