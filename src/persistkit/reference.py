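"""Published benchmark values from the Japanese claims study this pipeline re-implements.

The original analysis ran on a proprietary employer-insurance claims
database, so its raw data cannot ship here.  What can ship are the printed
summary tables — per-stratum patient counts, 12-month pre-index costs and
pre-to-post cost increases in thousand JPY — which serve as fixture inputs
for arithmetic-consistency checks: post-initiation totals must reconstruct
as pre + increase, component sums must match printed totals to rounding, and
group deltas must equal differences of group means.

Strata: ``naive``/``total`` population x ``all``/``persistent``/
``non_persistent`` group x drug (ADL, IFX, UST, subtotal; the secukinumab
arm was too small for cost reporting).  Component order: (total, IP, OP, RX).
"""
from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "population", "group", "drug", "n",
    "pre_total", "pre_IP", "pre_OP", "pre_RX",
    "inc_total", "inc_IP", "inc_OP", "inc_RX",
]

# fmt: off
_ROWS = [
    # population, group, drug, n, pre(total,IP,OP,RX), increase(total,IP,OP,RX)
    ("total", "all",            "ADL",      18,  760,  18, 513, 229,  1538,   95, 1077,  366),
    ("total", "all",            "IFX",      20,  950, 343, 301, 306,  2429,  601, 1958, -130),
    ("total", "all",            "UST",      37,  900, 254, 425, 221,  1865,  -37, 2011, -109),
    ("total", "all",            "subtotal", 77,  886, 235, 405, 246,  1907,  156, 1754,   -2),
    ("naive", "all",            "ADL",      14,  365,   0, 133, 232,  1853,  146, 1379,  328),
    ("naive", "all",            "IFX",      19,  916, 361, 261, 294,  2494,  633, 1974, -113),
    ("naive", "all",            "UST",      30,  603, 162, 216, 225,  2221,   21, 2296,  -96),
    ("naive", "all",            "subtotal", 64,  641, 188, 210, 244,  2187,  228, 1965,   -5),
    ("total", "persistent",     "ADL",       6, 1092,  55, 876, 161,  1606,  -55, 1365,  295),
    ("total", "persistent",     "IFX",       6, 1062, 603, 398,  61,  2246, -174, 2446,  -26),
    ("total", "persistent",     "UST",      29,  925, 315, 418, 192,  1875, -147, 2114,  -91),
    ("total", "persistent",     "subtotal", 42,  988, 340, 473, 175,  1883, -140, 2054,  -30),
    ("naive", "persistent",     "ADL",       4,  360,   0, 263,  97,  2433,    0, 2461,  -27),
    ("naive", "persistent",     "IFX",       6, 1062, 603, 398,  61,  2246, -174, 2446,  -26),
    ("naive", "persistent",     "UST",      23,  597, 201, 211, 186,  2211,  -98, 2380,  -71),
    ("naive", "persistent",     "subtotal", 33,  653, 250, 251, 152,  2244, -100, 2402,  -57),
    ("total", "non_persistent", "ADL",      12,  595,   0, 332, 263,  1504,  170,  932,  402),
    ("total", "non_persistent", "IFX",      14,  902, 231, 259, 412,  2507,  933, 1749, -175),
    ("total", "non_persistent", "UST",       8,  808,  32, 448, 328,  1828,  362, 1638, -172),
    ("total", "non_persistent", "subtotal", 35,  762, 108, 324, 330,  1937,  511, 1395,   31),
    ("naive", "non_persistent", "ADL",      10,  367,   0,  81, 286,  1620,  204,  946,  470),
    ("naive", "non_persistent", "IFX",      13,  848, 249, 198, 401,  2608, 1005, 1756, -153),
    ("naive", "non_persistent", "UST",       7,  621,  36, 232, 353,  2254,  414, 2021, -181),
    ("naive", "non_persistent", "subtotal", 31,  629, 122, 166, 341,  2126,  577, 1499,   50),
]
# fmt: on

#: Binary 12-month persistence in the BT-naive cost population: 33 of 64 persistent.
NAIVE_COST_POPULATION = {"n": 64, "persistent": 33, "non_persistent": 31}


def published_cost_table() -> pd.DataFrame:
    """The printed cost-summary rows (thousand JPY) as a tidy DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reconstruct_post(row: pd.Series) -> dict[str, float]:
    """Post-initiation 12-month costs implied by a printed row: pre + increase."""
    return {
        comp: float(row[f"pre_{comp}"] + row[f"inc_{comp}"])
        for comp in ("total", "IP", "OP", "RX")
    }


def published_row(population: str, group: str, drug: str) -> pd.Series:
    df = published_cost_table()
    match = df[(df.population == population) & (df.group == group) & (df.drug == drug)]
    if len(match) != 1:
        raise KeyError(f"no published row for ({population}, {group}, {drug})")
    return match.iloc[0]


def component_sum_consistency() -> pd.DataFrame:
    """Deviation of printed component sums from printed totals, per row.

    Rounding to thousand JPY bounds each deviation by the number of summed
    components; in the printed tables every deviation is within 1.
    """
    df = published_cost_table()
    out = df[["population", "group", "drug"]].copy()
    out["pre_deviation"] = df["pre_IP"] + df["pre_OP"] + df["pre_RX"] - df["pre_total"]
    out["inc_deviation"] = df["inc_IP"] + df["inc_OP"] + df["inc_RX"] - df["inc_total"]
    return out
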