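"""Eligibility and inclusion rules applied to raw series before recurrence analysis.

Two rules operate on the same 30 °C skin-contact threshold: samples below the
threshold are dropped (they indicate the sensor was off the skin), and a
subject-setting whose series is mostly below the threshold is excluded
outright.  The retained series is treated as a contiguous sequence; positions
of the dropped samples are recorded in the report for audit but the series is
not re-embedded with time-aware lags.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io_sensors import TemperatureSeries, ValidationError

DEFAULT_THRESHOLD_C = 30.0
DEFAULT_EXCLUSION_FRACTION = 0.80


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the inclusion filter for one subject-setting."""

    subject_id: str
    setting: str
    n_raw: int
    n_below_threshold: int
    fraction_below: float
    eligible: bool
    n_retained: int
    threshold_c: float
    exclusion_fraction: float


def apply_inclusion_filter(
    series: TemperatureSeries,
    threshold_c: float = DEFAULT_THRESHOLD_C,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
) -> tuple[TemperatureSeries, FilterReport]:
    """Drop sub-threshold samples and decide eligibility.

    Returns the filtered series (values >= ``threshold_c``, original order)
    and a :class:`FilterReport`.  ``eligible`` is False when the fraction of
    sub-threshold samples reaches ``exclusion_fraction``; downstream stages
    must refuse ineligible records.
    """
    if len(series) == 0:
        raise ValidationError(f"{series.subject_id}/{series.setting}: empty series")
    keep = series.values >= threshold_c
    n_raw = len(series)
    n_below = int(np.count_nonzero(~keep))
    fraction_below = n_below / n_raw
    eligible = fraction_below < exclusion_fraction
    filtered = TemperatureSeries(
        subject_id=series.subject_id,
        setting=series.setting,
        timestamps=series.timestamps[keep],
        values=series.values[keep],
    ) if keep.any() else series  # fully-excluded series returned unfiltered; it is ineligible anyway
    report = FilterReport(
        subject_id=series.subject_id,
        setting=series.setting,
        n_raw=n_raw,
        n_below_threshold=n_below,
        fraction_below=fraction_below,
        eligible=eligible,
        n_retained=int(np.count_nonzero(keep)),
        threshold_c=threshold_c,
        exclusion_fraction=exclusion_fraction,
    )
    return filtered, report


def summarize_cohort(reports: Iterable[FilterReport]) -> pd.DataFrame:
    """Per-subject eligibility: a subject is eligible iff every setting is.

    Returns one row per subject with ``eligible`` (AND over settings) plus the
    per-setting flags; the attribute ``.attrs["n_eligible"]`` carries the count
    of eligible subjects.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no filter reports supplied")
    df = pd.DataFrame([asdict(r) for r in reports])
    if df.duplicated(subset=["subject_id", "setting"]).any():
        raise ValidationError("duplicated subject-setting in filter reports")
    per_subject = (
        df.groupby("subject_id", sort=True)
        .agg(n_settings=("setting", "size"), eligible=("eligible", "all"))
        .reset_index()
    )
    per_subject.attrs["n_eligible"] = int(per_subject["eligible"].sum())
    return per_subject


def reports_to_frame(reports: Iterable[FilterReport]) -> pd.DataFrame:
    """Flatten reports for CSV output alongside the metrics table."""
    return pd.DataFrame([asdict(r) for r in reports])


def hormone_outlier_rule(
    hormones: pd.DataFrame, analyte: str, cutoff: float | None = None
) -> set[str]:
    """Optional analyte-level exclusion: subjects whose mean analyte value
    exceeds ``cutoff`` are flagged for exclusion.  Off (empty set) when
    ``cutoff`` is None — the rule exists for parity with ad-hoc exclusions of
    implausibly high hormone readings, but no general threshold is defensible
    as a default.
    """
    if cutoff is None:
        return set()
    means = hormones.groupby("subject_id")[analyte].mean()
    return set(means.index[means > cutoff])
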