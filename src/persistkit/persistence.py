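"""Treatment-episode construction from refill claims.

An episode runs from the index claim of a unit's biologic until the first of:

* **gap discontinuation** — the span from one index-drug claim to the next
  (or to the end of observation, if no further claim exists) exceeds the
  drug's non-refill period (treatment interval + medication gap).  The event
  is dated at the end of supplied therapy, ``last claim + treatment
  interval``, so the event time does not move with the gap parameter;
* **switch discontinuation** — a claim of a different biologic appears
  before the index drug's next claim and before a gap is provable; the event
  is dated at that claim;
* **censoring** — observation ends while the remaining claim-free window is
  still shorter than the non-refill period, so no discontinuation can be
  proven.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import GapPolicy

GAP = "gap_discontinued"
SWITCH = "switch_discontinued"
CENSORED = "censored"

EPISODE_COLUMNS = [
    "unit_id", "patient_id", "drug", "index_day", "status", "end_day",
    "persistent_12m", "persistent_24m",
]


@dataclass(frozen=True)
class TreatmentEpisode:
    unit_id: str
    patient_id: str
    drug: str
    index_day: int
    status: str  # GAP | SWITCH | CENSORED
    end_day: int  # days since index (event or censor time)

    @property
    def event(self) -> bool:
        return self.status != CENSORED


def build_episode(
    unit, claims: pd.DataFrame, policy: GapPolicy, switch_on_same_day: bool = True
) -> TreatmentEpisode:
    """Construct the treatment episode for one patient unit.

    ``unit`` is a row (attribute access) with unit_id, patient_id, drug,
    index_day, obs_end.  ``claims`` is the drug-claim table (any superset of
    the patient's claims).  ``switch_on_same_day`` controls the tie-break when
    another biologic is claimed on the same day as an index-drug claim.
    """
    drug = unit.drug
    interval = policy.interval(drug)
    non_refill = policy.non_refill_days(drug)
    mine = claims[(claims["patient_id"] == unit.patient_id)]
    own = sorted(mine.loc[(mine["bt_class"] == drug) & (mine["date"] >= unit.index_day), "date"])
    if not own or own[0] != unit.index_day:
        raise ValueError(
            f"unit {unit.unit_id}: no claim of {drug} on the index day {unit.index_day}"
        )
    others = sorted(mine.loc[(mine["bt_class"] != drug) & (mine["date"] >= unit.index_day), "date"])

    def _episode(status: str, end_abs: int) -> TreatmentEpisode:
        return TreatmentEpisode(unit.unit_id, unit.patient_id, drug,
                                int(unit.index_day), status, int(end_abs - unit.index_day))

    for k, claim in enumerate(own):
        nxt = own[k + 1] if k + 1 < len(own) else None
        horizon = nxt if nxt is not None else int(unit.obs_end)
        deadline = claim + non_refill  # last day before the gap becomes provable
        switch_day = None
        for s in others:
            if s < claim or (s == claim and not switch_on_same_day):
                continue
            if nxt is not None and s >= nxt:
                break
            switch_day = s
            break
        if switch_day is not None and switch_day <= deadline:
            return _episode(SWITCH, switch_day)
        if horizon - claim > non_refill:
            return _episode(GAP, claim + interval)
    return _episode(CENSORED, int(unit.obs_end))


def build_episodes(
    units: pd.DataFrame, claims: pd.DataFrame, policy: GapPolicy, **kwargs
) -> pd.DataFrame:
    """Episode table for all units, with 12/24-month persistence flags.

    The persistence flags are pd.NA when the unit lacks the corresponding
    post-index observation window (365 or 730 days).
    """
    rows = []
    for unit in units.itertuples(index=False):
        ep = build_episode(unit, claims, policy, **kwargs)
        followup = int(unit.obs_end) - int(unit.index_day)
        rows.append({
            "unit_id": ep.unit_id,
            "patient_id": ep.patient_id,
            "drug": ep.drug,
            "index_day": ep.index_day,
            "status": ep.status,
            "end_day": ep.end_day,
            "persistent_12m": classify_persistence(ep, 365) if followup >= 365 else pd.NA,
            "persistent_24m": classify_persistence(ep, 730) if followup >= 730 else pd.NA,
        })
    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    for col in ("persistent_12m", "persistent_24m"):
        df[col] = df[col].astype("boolean")
    return df


def classify_persistence(episode: TreatmentEpisode, horizon_days: int = 365) -> bool:
    """True iff no discontinuation event occurs before ``horizon_days``."""
    return not (episode.event and episode.end_day < horizon_days)


def classify_12m_persistence(episode: TreatmentEpisode, followup_days: int) -> bool:
    """Binary 12-month persistence; requires a full year of post-index observation."""
    if followup_days < 365:
        raise ValueError(
            f"unit {episode.unit_id}: 12-month persistence needs >=365 days of "
            f"post-index observation, got {followup_days}"
        )
    return classify_persistence(episode, 365)


def sensitivity_grid(
    units: pd.DataFrame, claims: pd.DataFrame, policies: list[GapPolicy]
) -> pd.DataFrame:
    """12-month persistence proportion per (drug, gap policy).

    Only units with at least 365 days of post-index observation enter the
    denominators, matching the binary-persistence eligibility rule.
    """
    if not policies:
        raise ValueError("at least one gap policy is required")
    eligible = units[(units["obs_end"] - units["index_day"]) >= 365]
    rows = []
    for policy in policies:
        episodes = build_episodes(eligible, claims, policy)
        for drug, grp in episodes.groupby("drug"):
            n = len(grp)
            n_persistent = int(grp["persistent_12m"].sum())
            rows.append({
                "policy": policy.label,
                "drug": drug,
                "n": n,
                "n_persistent": n_persistent,
                "proportion": n_persistent / n if n else float("nan"),
            })
    return pd.DataFrame(rows)
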