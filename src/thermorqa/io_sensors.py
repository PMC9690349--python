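"""Readers and writers for the tabular formats the pipeline touches.

Sensor series, cohort manifest and hormone tables are plain CSV with a header
row.  Column names vary between deposits, so every reader takes a *dialect*
mapping from logical column names to the names actually present in the file.

Timestamps are accepted either as ISO-8601 strings or as integer minutes and
are normalised internally to an integer minute index from the series start:
the recurrence machinery needs only order and spacing, absolute clock time
matters only for plotting.  Readers never interpolate, resample or drop data
silently; every irregularity is surfaced in the returned gap summary or raised
as a validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SETTINGS = ("urban", "mountainous")
GROUPS = ("first_urban", "first_mountainous")
SAMPLE_TYPES = ("first_morning", "night")
ANALYTES = ("leptin", "adiponectin", "cortisol")

#: default logical-to-physical column names for sensor files
SERIES_DIALECT: Mapping[str, str] = {"timestamp": "t", "temperature": "temp"}


class FormatError(ValueError):
    """A file does not have the expected columns or cell types."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


@dataclass(frozen=True)
class GapSummary:
    """Spacing irregularities of a nominally 1-minute series."""

    n_gaps: int
    gap_positions: tuple[int, ...]  # index of the sample *after* each gap
    gap_minutes: tuple[int, ...]    # spacing at those positions (> nominal)
    nominal_spacing: int = 1


@dataclass(frozen=True)
class TemperatureSeries:
    """One subject-setting skin (or personal-air) temperature record.

    ``timestamps`` are minutes from the series start, strictly increasing at a
    nominal 1-minute spacing; ``values`` are temperatures in degrees Celsius.
    """

    subject_id: str
    setting: str
    timestamps: np.ndarray
    values: np.ndarray
    gaps: GapSummary = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if self.setting not in SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}; expected one of {SETTINGS}")
        if ts.shape != vals.shape or ts.ndim != 1:
            raise ValidationError("timestamps and values must be 1-d arrays of equal length")
        if len(ts) < 1:
            raise ValidationError("series must contain at least one sample")
        diffs = np.diff(ts)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 2  # 1-based data row of the offender
            raise ValidationError(f"timestamps not strictly increasing at row {row}")
        if not np.all(np.isfinite(vals)):
            row = int(np.argmax(~np.isfinite(vals))) + 1
            raise ValidationError(f"non-finite temperature value at row {row}")
        if self.gaps is None:
            pos = np.nonzero(diffs > 1)[0] + 1
            object.__setattr__(
                self,
                "gaps",
                GapSummary(
                    n_gaps=int(pos.size),
                    gap_positions=tuple(int(i) for i in pos),
                    gap_minutes=tuple(int(diffs[i - 1]) for i in pos),
                ),
            )

    def __len__(self) -> int:
        return len(self.values)


def _parse_timestamps(raw: pd.Series, path: Path) -> np.ndarray:
    """Normalise a timestamp column to integer minutes from the first sample."""
    if pd.api.types.is_numeric_dtype(raw):
        ts = raw.to_numpy()
        if not np.all(np.isfinite(ts)):
            raise FormatError(f"{path}: non-numeric timestamp cell")
        return np.asarray(np.round(ts), dtype=np.int64)
    try:
        parsed = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: timestamps are neither numeric minutes nor ISO-8601: {exc}") from exc
    minutes = (parsed - parsed.iloc[0]).dt.total_seconds() / 60.0
    return np.asarray(np.round(minutes.to_numpy()), dtype=np.int64)


def read_series(
    path: str | Path,
    *,
    subject_id: str,
    setting: str,
    dialect: Mapping[str, str] | None = None,
) -> TemperatureSeries:
    """Read one sensor series from CSV and validate it.

    Parameters
    ----------
    path
        CSV file with a header row.
    subject_id, setting
        Identity of the record; series files carry no identity columns.
    dialect
        Maps the logical names ``timestamp`` and ``temperature`` to the column
        names present in the file.  Defaults to ``{"timestamp": "t",
        "temperature": "temp"}``.
    """
    path = Path(path)
    dialect = dict(SERIES_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in (dialect["timestamp"], dialect["temperature"]) if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    temp = df[dialect["temperature"]]
    if temp.isna().any():
        row = int(temp.isna().idxmax()) + 2
        raise ValidationError(f"{path}: empty temperature cell at row {row}; gaps are not imputed")
    return TemperatureSeries(
        subject_id=subject_id,
        setting=setting,
        timestamps=_parse_timestamps(df[dialect["timestamp"]], path),
        values=temp.to_numpy(dtype=np.float64),
    )


def write_series(series: TemperatureSeries, path: str | Path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a series as CSV in the given dialect (round-trips with read_series)."""
    dialect = dict(SERIES_DIALECT if dialect is None else dialect)
    df = pd.DataFrame({dialect["timestamp"]: series.timestamps, dialect["temperature"]: series.values})
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest.

    Expected columns: subject_id, group, age, sex, setting, series_file
    (one row per subject-setting).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    required = {"subject_id", "group", "age", "sex", "setting", "series_file"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"{path}: unknown group value(s) {sorted(bad_group)}")
    bad_setting = set(df["setting"]) - set(SETTINGS)
    if bad_setting:
        raise ValidationError(f"{path}: unknown setting value(s) {sorted(bad_setting)}")
    if (df["age"] <= 0).any():
        raise ValidationError(f"{path}: ages must be positive")
    dup = df.duplicated(subset=["subject_id", "setting"])
    if dup.any():
        offender = df.loc[dup, ["subject_id", "setting"]].iloc[0]
        raise ValidationError(
            f"{path}: more than one series for subject {offender['subject_id']} in {offender['setting']}"
        )
    return df


def read_hormones(path: str | Path) -> pd.DataFrame:
    """Read the hormone table.

    Expected columns: subject_id, setting, sample_type, then per analyte a
    value column (``leptin`` ...), a ``<analyte>_below_lod`` flag and a
    ``<analyte>_lod`` column, plus ``creatinine``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    required = {"subject_id", "setting", "sample_type", "creatinine"}
    required |= set(ANALYTES)
    required |= {f"{a}_below_lod" for a in ANALYTES} | {f"{a}_lod" for a in ANALYTES}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: hormone table missing column(s) {sorted(missing)}")
    bad_sample = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad_sample:
        raise ValidationError(f"{path}: unknown sample_type value(s) {sorted(bad_sample)}")
    for a in ANALYTES:
        if (df[a] < 0).any():
            raise ValidationError(f"{path}: negative {a} concentration")
        flagged = df[f"{a}_below_lod"].astype(bool)
        if (df.loc[flagged, a] > df.loc[flagged, f"{a}_lod"]).any():
            raise ValidationError(f"{path}: {a} flagged below LOD but reported above it")
    return df


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write any tabular result (metrics, model tables, reports) as CSV.

    Refuses empty input: an empty output file would hide an upstream failure.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if len(df) == 0:
        raise ValidationError(f"refusing to write empty table to {path}")
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(Path(path), dtype={"subject_id": str}, float_precision="round_trip")
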