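"""Participant-level cohort table: typed columns, CSV round-trip, summaries.

The cohort holds one row per participant: the childhood group label,
demographics (sex, age, childhood SES class 1-3, education class 1-3,
number-of-birth-risks stratum), the adult ADHD self-report screener total
(ASRS, 0-24), and one column per battery measure.  Missing values are
kept missing — an empty CSV cell (or ``NA``) reads back as NaN, never 0.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import BatteryConfig, default_battery

__all__ = [
    "GROUPS",
    "SEXES",
    "BIRTH_RISK_STRATA",
    "CohortError",
    "GroupSummary",
    "CohortTable",
    "load_cohort",
    "write_cohort",
    "summarize_group",
]

GROUPS = ("cADHD", "cAP", "Non-cAP", "Control")
SEXES = ("female", "male")
BIRTH_RISK_STRATA = ("one", "two", "three_to_five", "none")
DEMO_COLUMNS = ["id", "group", "sex", "age", "ses", "education",
                "birth_risks", "asrs"]
ASRS_RANGE = (0, 24)


class CohortError(ValueError):
    """Malformed cohort table."""


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n / mean / SD of one measure (sample SD, n-1 denominator)."""

    group: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class CohortTable:
    """A validated cohort: a DataFrame plus the battery it conforms to.

    ``data`` carries the demographic columns followed by one float column
    per battery measure; NaN encodes a missing cell.
    """

    data: pd.DataFrame
    battery: BatteryConfig

    def __post_init__(self) -> None:
        _validate(self.data, self.battery)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def scores(self) -> pd.DataFrame:
        """The participants x measures score block (view)."""
        return self.data[self.battery.measure_names]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return replace(self, data=data)

    def group_subset(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise CohortError(f"unknown group {group!r}")
        return self.data[self.data["group"] == group]


def _validate(df: pd.DataFrame, battery: BatteryConfig) -> None:
    missing_cols = [c for c in DEMO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort table missing column(s) {missing_cols}")
    extra = [c for c in df.columns
             if c not in DEMO_COLUMNS and c not in battery.measure_names]
    if extra:
        raise CohortError(f"score column(s) not in battery: {extra}")
    absent = [m for m in battery.measure_names if m not in df.columns]
    if absent:
        raise CohortError(f"battery measure column(s) missing: {absent}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise CohortError(f"duplicate participant id(s): {dupes}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(
            f"row {row}: unknown group label {df['group'].iloc[row]!r} "
            f"(expected one of {list(GROUPS)})"
        )
    bad = df["sex"].notna() & ~df["sex"].isin(SEXES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(f"row {row}: unknown sex {df['sex'].iloc[row]!r}")
    bad = df["birth_risks"].notna() & ~df["birth_risks"].isin(BIRTH_RISK_STRATA)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortError(
            f"row {row}: unknown birth_risks {df['birth_risks'].iloc[row]!r}"
        )
    ctrl_bad = (df["group"] == "Control") & (df["birth_risks"] != "none")
    if ctrl_bad.any():
        row = int(np.flatnonzero(ctrl_bad.to_numpy())[0])
        raise CohortError(
            f"row {row}: Control participants must have birth_risks='none'"
        )
    asrs = pd.to_numeric(df["asrs"], errors="coerce")
    out = asrs.notna() & ((asrs < ASRS_RANGE[0]) | (asrs > ASRS_RANGE[1]))
    if out.any():
        row = int(np.flatnonzero(out.to_numpy())[0])
        raise CohortError(
            f"row {row}: ASRS score {asrs.iloc[row]} outside [0, 24]"
        )
    for col in ("ses", "education"):
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.notna() & ~vals.isin([1, 2, 3])
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise CohortError(
                f"row {row}: {col} class {df[col].iloc[row]!r} not in 1-3"
            )


def load_cohort(table_doc, battery: BatteryConfig | None = None) -> CohortTable:
    """Read a cohort CSV (or accept a DataFrame) against a battery.

    Empty cells and the sentinel ``NA`` are read as missing.  Score
    columns are coerced to float; a non-numeric score cell raises
    :class:`CohortError` naming the row and column.
    """
    if battery is None:
        battery = default_battery()
    if isinstance(table_doc, pd.DataFrame):
        df = table_doc.copy()
    else:
        df = pd.read_csv(table_doc, na_values=["NA"], keep_default_na=True,
                         dtype={"id": str})
    for col in battery.measure_names + ["asrs", "age", "ses", "education"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"row {row}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}"
            )
        df[col] = coerced.astype(float)
    df["id"] = df["id"].astype(str)
    return CohortTable(data=df.reset_index(drop=True), battery=battery)


def write_cohort(cohort: CohortTable, path) -> Path:
    """Write the cohort as UTF-8 CSV; missing cells serialize as empty."""
    path = Path(path)
    cols = DEMO_COLUMNS + cohort.battery.measure_names
    cohort.data[cols].to_csv(path, index=False, na_rep="")
    return path


def summarize_group(cohort: CohortTable, measure: str) -> list[GroupSummary]:
    """Per-group n / mean / sample SD of one measure over non-missing values.

    Groups with no observed value get ``n=0`` and NaN mean/SD.
    """
    cohort.battery.measure(measure)  # raises on unknown name
    out = []
    present = [g for g in GROUPS if (cohort.groups == g).any()]
    for g in present:
        vals = cohort.group_subset(g)[measure].dropna()
        n = len(vals)
        out.append(GroupSummary(
            group=g,
            n=n,
            mean=float(vals.mean()) if n else float("nan"),
            sd=float(vals.std(ddof=1)) if n > 1 else float("nan"),
        ))
    return out
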