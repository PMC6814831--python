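"""Reading, validation and writing of the tidy trial-table schemas.

CSV schemas (UTF-8, header row, comma-separated):

fr_trials.csv
    predator, prey, density, eaten, is_control (0/1), replicate_id

switch_trials.csv
    predator, prop_invader, n_invader_0, n_native_0, eaten_invader,
    eaten_native, is_control, replicate_id

Validation is strict: missing columns, counts eaten exceeding counts
offered, or negative counts are schema errors that name the offending
rows.  Control rows are checked against the expectation that no control
prey die (deaths in predator trials are then attributable to predation);
a failed control check blocks downstream analysis unless explicitly
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "FR_COLUMNS",
    "SWITCH_COLUMNS",
    "read_fr_trials",
    "read_switch_trials",
    "write_fr_trials",
    "write_switch_trials",
    "ValidationReport",
    "validate_controls",
]

FR_COLUMNS = ["predator", "prey", "density", "eaten", "is_control", "replicate_id"]
SWITCH_COLUMNS = [
    "predator",
    "prop_invader",
    "n_invader_0",
    "n_native_0",
    "eaten_invader",
    "eaten_native",
    "is_control",
    "replicate_id",
]


class SchemaError(ValueError):
    """Input table does not conform to the published CSV contract."""


def _load(path, required) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return df


def _offending(mask) -> str:
    rows = [str(i + 2) for i in mask[mask].index]  # +2: header + 1-based
    return ", ".join(rows)


def read_fr_trials(path) -> pd.DataFrame:
    """Load and validate a single-prey trial table."""
    df = _load(path, FR_COLUMNS)
    for col in ("density", "eaten", "is_control", "replicate_id"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued: {exc}") from None
    bad = df["density"] <= 0
    if bad.any():
        raise SchemaError(f"non-positive density in file rows: {_offending(bad)}")
    bad = (df["eaten"] < 0) | (df["eaten"] > df["density"])
    if bad.any():
        raise SchemaError(f"eaten outside [0, density] in file rows: {_offending(bad)}")
    if not df["is_control"].isin([0, 1]).all():
        raise SchemaError("is_control must be 0 or 1")
    return df[FR_COLUMNS]


def read_switch_trials(path) -> pd.DataFrame:
    """Load and validate a two-prey switching trial table."""
    df = _load(path, SWITCH_COLUMNS)
    int_cols = ("n_invader_0", "n_native_0", "eaten_invader", "eaten_native", "is_control", "replicate_id")
    for col in int_cols:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued: {exc}") from None
    df["prop_invader"] = pd.to_numeric(df["prop_invader"], errors="coerce")
    if df["prop_invader"].isna().any() or not df["prop_invader"].between(0, 1).all():
        raise SchemaError("prop_invader must be a number in [0, 1]")
    for eaten, start in (("eaten_invader", "n_invader_0"), ("eaten_native", "n_native_0")):
        bad = (df[eaten] < 0) | (df[eaten] > df[start])
        if bad.any():
            raise SchemaError(f"{eaten} outside [0, {start}] in file rows: {_offending(bad)}")
    if not df["is_control"].isin([0, 1]).all():
        raise SchemaError("is_control must be 0 or 1")
    return df[SWITCH_COLUMNS]


def write_fr_trials(df: pd.DataFrame, path) -> None:
    df[FR_COLUMNS].to_csv(path, index=False)


def write_switch_trials(df: pd.DataFrame, path) -> None:
    df[SWITCH_COLUMNS].to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Outcome of structural + control checks on a loaded dataset."""

    row_counts: dict = field(default_factory=dict)
    control_ok: bool = True
    control_violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.control_ok


def validate_controls(df: pd.DataFrame, eaten_cols=("eaten",)) -> ValidationReport:
    """Check that every control row records zero deaths.

    ``eaten_cols`` lists the consumption columns to check (one for FR
    tables, two for switching tables).  The report carries per-group row
    counts, violating file rows, and a warning if no controls are present.
    """
    report = ValidationReport()
    group_cols = [c for c in ("predator", "prey") if c in df.columns]
    if group_cols:
        report.row_counts = {
            (key if isinstance(key, str) else "|".join(map(str, key))): int(n)
            for key, n in df.groupby(group_cols).size().items()
        }
    controls = df[df["is_control"] == 1]
    if controls.empty:
        report.warnings.append("no control rows present")
        return report
    violated = controls[[*eaten_cols]].sum(axis=1) > 0
    if violated.any():
        report.control_ok = False
        report.control_violations = [int(i + 2) for i in violated[violated].index]
    return report
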