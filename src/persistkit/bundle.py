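"""The four-table claims bundle and its delimited-text round trip.

In memory every date column holds integer day offsets from
:data:`persistkit.config.DATE_ORIGIN`; on disk the same columns are written
as ISO-8601 calendar dates so the CSVs read naturally as claims extracts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DATE_ORIGIN

ENROLLMENT_COLUMNS = ["patient_id", "obs_start", "obs_end", "age", "sex"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "icd10"]
DRUG_CLAIM_COLUMNS = ["patient_id", "date", "drug_code", "bt_class", "setting"]
COST_COLUMNS = ["patient_id", "date", "amount_jpy", "category", "is_bt_drug_cost"]

_DATE_COLS = {
    "enrollment": ["obs_start", "obs_end"],
    "diagnoses": ["date"],
    "drug_claims": ["date"],
    "costs": ["date"],
}
_SCHEMAS = {
    "enrollment": ENROLLMENT_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "drug_claims": DRUG_CLAIM_COLUMNS,
    "costs": COST_COLUMNS,
}


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in _SCHEMAS[table]})


@dataclass
class ClaimsBundle:
    """Enrollment, diagnosis, drug-claim and cost tables for one cohort."""

    enrollment: pd.DataFrame = field(default_factory=lambda: _empty("enrollment"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty("diagnoses"))
    drug_claims: pd.DataFrame = field(default_factory=lambda: _empty("drug_claims"))
    costs: pd.DataFrame = field(default_factory=lambda: _empty("costs"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "enrollment": self.enrollment,
            "diagnoses": self.diagnoses,
            "drug_claims": self.drug_claims,
            "costs": self.costs,
        }

    def validate(self) -> None:
        """Check schema, referential integrity and enrollment-window containment."""
        for name, df in self.tables().items():
            missing = [c for c in _SCHEMAS[name] if c not in df.columns]
            if missing:
                raise ValueError(f"table {name!r} is missing column(s) {missing}")
        known = set(self.enrollment["patient_id"])
        for name in ("diagnoses", "drug_claims", "costs"):
            df = self.tables()[name]
            if len(df):
                orphans = set(df["patient_id"]) - known
                if orphans:
                    raise ValueError(
                        f"table {name!r} references unknown patient(s): {sorted(orphans)[:5]}"
                    )
        if len(self.enrollment):
            win = self.enrollment.set_index("patient_id")[["obs_start", "obs_end"]]
            for name in ("diagnoses", "drug_claims", "costs"):
                df = self.tables()[name]
                if not len(df):
                    continue
                joined = df.join(win, on="patient_id")
                bad = (joined["date"] < joined["obs_start"]) | (joined["date"] > joined["obs_end"])
                if bad.any():
                    row = joined[bad].index[0]
                    raise ValueError(
                        f"table {name!r} row {row} has a date outside the patient's enrollment window"
                    )

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(
            a.reset_index(drop=True).equals(b.reset_index(drop=True))
            for a, b in zip(self.tables().values(), other.tables().values())
        )


def _days_to_iso(days: pd.Series) -> pd.Series:
    origin = pd.Timestamp(DATE_ORIGIN)
    return (origin + pd.to_timedelta(days.astype(int), unit="D")).dt.strftime("%Y-%m-%d")


def _iso_to_days(dates: pd.Series, table: str, column: str) -> pd.Series:
    origin = pd.Timestamp(DATE_ORIGIN)
    parsed = pd.to_datetime(dates, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(
            f"table {table!r}, column {column!r}: unparseable date "
            f"{dates.iloc[row]!r} at row {row}"
        )
    return (parsed - origin).dt.days.astype(np.int64)


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write the four tables as ``<directory>/<table>.csv`` with ISO dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables().items():
        out = df.loc[:, _SCHEMAS[name]].copy()
        for col in _DATE_COLS[name]:
            if len(out):
                out[col] = _days_to_iso(out[col])
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Read ``enrollment/diagnoses/drug_claims/costs.csv`` back into day offsets."""
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, columns in _SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str, "icd10": str})
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} is missing column(s) {missing}")
        if not len(df):
            frames[name] = _empty(name)
            continue
        for col in _DATE_COLS[name]:
            df[col] = _iso_to_days(df[col], name, col)
        if "is_bt_drug_cost" in df.columns:
            df["is_bt_drug_cost"] = df["is_bt_drug_cost"].astype(bool)
        if "amount_jpy" in df.columns:
            df["amount_jpy"] = df["amount_jpy"].astype(float)
        if "age" in df.columns:
            df["age"] = df["age"].astype(int)
        frames[name] = df.loc[:, columns]
    return ClaimsBundle(**frames)
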