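"""Twelve-month pre/post cost windows and persistence contrasts.

Windows are anchored on the index date: the pre window is the 365 days
``[index-365, index-1]`` and the post window ``[index, index+364]`` — the
index day itself belongs to the post window because the first biologic
administration is a post-initiation cost.  Components: IP = all
inpatient-category amounts, OP = all outpatient-category amounts (both
include biologic drug costs, billed wherever they were administered), and
RX = pharmacy amounts excluding biologics.  Amounts are stored in JPY;
reports round to thousand JPY.
"""
from __future__ import annotations

import pandas as pd

COMPONENTS = ["IP", "OP", "RX_nonBT", "total"]

PRE_DAYS = 365
POST_DAYS = 365


def window_costs(unit, costs: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Pre/post component sums (JPY) for one cost-eligible unit.

    ``unit`` needs patient_id, index_day, obs_start, obs_end.  Raises when the
    unit lacks the full 24-month window.
    """
    index = int(unit.index_day)
    if unit.obs_start > index - PRE_DAYS or unit.obs_end < index + POST_DAYS:
        raise ValueError(
            f"unit {unit.unit_id}: cost windows need 12 months of observation "
            "on both sides of the index date"
        )
    mine = costs[costs["patient_id"] == unit.patient_id]
    out = {}
    for window, lo, hi in (("pre", index - PRE_DAYS, index - 1),
                           ("post", index, index + POST_DAYS - 1)):
        w = mine[(mine["date"] >= lo) & (mine["date"] <= hi)]
        ip = float(w.loc[w["category"] == "IP", "amount_jpy"].sum())
        op = float(w.loc[w["category"] == "OP", "amount_jpy"].sum())
        rx = float(w.loc[(w["category"] == "RX") & (~w["is_bt_drug_cost"]), "amount_jpy"].sum())
        out[window] = {"IP": ip, "OP": op, "RX_nonBT": rx, "total": ip + op + rx}
    return out


def window_cost_table(units: pd.DataFrame, costs: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-unit window sums: one row per (unit, window)."""
    rows = []
    for unit in units.itertuples(index=False):
        summaries = window_costs(unit, costs)
        for window, comp in summaries.items():
            rows.append({"unit_id": unit.unit_id, "window": window, **comp})
    return pd.DataFrame(rows, columns=["unit_id", "window", *COMPONENTS])


def cost_increase(pre: dict[str, float], post: dict[str, float],
                  unit_id_pre: str | None = None, unit_id_post: str | None = None) -> dict[str, float]:
    """Componentwise post-minus-pre change; may be negative."""
    if unit_id_pre is not None and unit_id_pre != unit_id_post:
        raise ValueError(f"mismatched units: {unit_id_pre!r} vs {unit_id_post!r}")
    return {c: post[c] - pre[c] for c in COMPONENTS}


def contrast_by_persistence(
    units: pd.DataFrame, episodes: pd.DataFrame, window_table: pd.DataFrame
) -> pd.DataFrame:
    """Mean pre costs and cost increases by drug x naive-stratum x persistence.

    ``units`` must carry a boolean ``naive`` column; persistence comes from
    the episode table's ``persistent_12m``.  Output rows cover each drug plus
    a ``subtotal`` pseudo-drug, for the naive stratum and the total
    population, each split into persistent / non_persistent groups, with a
    delta row (non-persistent minus persistent means).  Empty groups are
    emitted with n = 0 and NaN means.
    """
    wide = window_table.pivot(index="unit_id", columns="window", values=COMPONENTS)
    meta = units.set_index("unit_id")[["drug", "naive"]].join(
        episodes.set_index("unit_id")["persistent_12m"]
    )
    rows = []
    for stratum, selector in (("naive", meta["naive"]), ("total", pd.Series(True, index=meta.index))):
        pool = meta[selector.astype(bool)]
        for drug in [*sorted(pool["drug"].unique()), "subtotal"]:
            sub = pool if drug == "subtotal" else pool[pool["drug"] == drug]
            group_means = {}
            for label, persistent in (("persistent", True), ("non_persistent", False)):
                ids = sub.index[sub["persistent_12m"].astype("boolean") == persistent]
                grp = wide.loc[wide.index.intersection(ids)]
                means = {}
                for comp in COMPONENTS:
                    pre_mean = grp[(comp, "pre")].mean() if len(grp) else float("nan")
                    inc_mean = (grp[(comp, "post")] - grp[(comp, "pre")]).mean() if len(grp) else float("nan")
                    means[f"pre_{comp}"] = pre_mean
                    means[f"increase_{comp}"] = inc_mean
                group_means[label] = means
                rows.append({"stratum": stratum, "drug": drug, "group": label,
                             "n": int(len(grp)), **means})
            delta = {k: group_means["non_persistent"][k] - group_means["persistent"][k]
                     for k in group_means["persistent"]}
            rows.append({"stratum": stratum, "drug": drug, "group": "delta", "n": pd.NA, **delta})
    return pd.DataFrame(rows)


def to_thousand_jpy(value: float) -> float:
    """Report-time rounding of a JPY amount to integer thousand JPY."""
    return round(value / 1000.0)
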