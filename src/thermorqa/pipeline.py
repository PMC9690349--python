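"""End-to-end orchestration: cohort RQA metric tables and the full analysis.

These helpers connect the modules the way the study design dictates: raw
series → inclusion filter → recurrence metrics per subject-setting →
log transforms, paired tests, PCA composite and mixed models.  The CLI and
the acceptance script are thin wrappers over these functions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import preprocess, stats
from .io_sensors import ANALYTES, ValidationError, read_series
from .rqa import EmbeddingConfig, RQAConfig, rqa_pipeline
from .stats import (
    DEFAULT_LOG_METRICS,
    HormoneAssociationModel,
    SettingEffectModel,
    log_transform_metrics,
    paired_tests_table,
    pca_pc1,
    prepare_hormones,
)

#: metrics modelled in Table-2 style (PC1 appended after PCA)
ANALYSIS_METRICS = DEFAULT_LOG_METRICS + ("TRE",)


def compute_cohort_metrics(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    embedding: EmbeddingConfig = EmbeddingConfig(),
    config: RQAConfig = RQAConfig(),
    threshold_c: float = preprocess.DEFAULT_THRESHOLD_C,
    exclusion_fraction: float = preprocess.DEFAULT_EXCLUSION_FRACTION,
    dialect: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RQA metrics for every eligible subject-setting in the manifest.

    Returns ``(metrics, filter_reports)``.  A subject ineligible in either
    setting is excluded from the metrics table entirely (paired design), but
    every series appears in the report table — nothing is dropped silently.
    """
    base_dir = Path(base_dir)
    reports = []
    series_by_key = {}
    for _, row in manifest.iterrows():
        series = read_series(base_dir / row["series_file"], subject_id=row["subject_id"],
                             setting=row["setting"], dialect=dialect)
        filtered, report = preprocess.apply_inclusion_filter(
            series, threshold_c=threshold_c, exclusion_fraction=exclusion_fraction)
        reports.append(report)
        series_by_key[(row["subject_id"], row["setting"])] = filtered
    eligibility = preprocess.summarize_cohort(reports)
    eligible_subjects = set(eligibility.loc[eligibility["eligible"], "subject_id"])

    rows = []
    for _, row in manifest.iterrows():
        key = (row["subject_id"], row["setting"])
        if row["subject_id"] not in eligible_subjects:
            continue
        m = rqa_pipeline(series_by_key[key], embedding, config)
        rows.append({
            "subject_id": row["subject_id"], "setting": row["setting"],
            "group": row["group"], "age": row["age"], "sex": row["sex"],
            **m.as_dict(),
            "radius_fraction": config.radius_fraction, "dimension": embedding.dimension,
            "lag": embedding.lag, "lmin": config.lmin, "border": config.border,
        })
    if not rows:
        raise ValidationError("no eligible subject-setting records")
    return pd.DataFrame(rows), preprocess.reports_to_frame(reports)


def analyze_cohort(
    metrics: pd.DataFrame,
    hormones: pd.DataFrame | None = None,
    ci_method: str = "wald-t",
    standardize_metric: bool = True,
) -> dict[str, pd.DataFrame]:
    """The full inferential layer on a metrics table (plus optional hormones).

    Log-transforms the positive metrics (TRE passes through), appends the PC1
    composite, then produces paired-test, PCA-summary, setting-model and
    (when hormones are given) hormone-model tables.  Subjects without both
    settings are excluded from the paired analyses; their ids are recorded in
    the returned ``excluded`` table.
    """
    counts = metrics.groupby("subject_id")["setting"].nunique()
    paired_subjects = set(counts.index[counts == 2])
    excluded = sorted(set(counts.index) - paired_subjects)
    data = metrics[metrics["subject_id"].isin(paired_subjects)].copy()
    if data.empty:
        raise ValidationError("no subjects with both settings present")

    logm = log_transform_metrics(data)
    pca = pca_pc1(logm, columns=list(ANALYSIS_METRICS))
    logm["PC1"] = pca.scores[:, 0]

    all_metrics = list(ANALYSIS_METRICS) + ["PC1"]
    out: dict[str, pd.DataFrame] = {}
    out["paired_tests"] = paired_tests_table(logm, all_metrics)
    out["pca_summary"] = pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(pca.eigenvalues))],
        "eigenvalue": pca.eigenvalues,
        "explained_variance": pca.explained_variance_ratio,
    })
    out["pca_loadings"] = pca.loadings.reset_index(names="metric")

    setting_rows = []
    for m in all_metrics:
        res = SettingEffectModel(logm, m, ci_method=ci_method).fit()
        setting_rows.append({"metric": m, "term": "mountainous", **{
            k: v for k, v in res.as_dict().items() if k not in ("outcome", "term")}})
    out["setting_models"] = pd.DataFrame(setting_rows)

    if hormones is not None:
        prepared = prepare_hormones(hormones)
        merged = prepared.merge(
            logm[["subject_id", "setting", "age"] + all_metrics],
            on=["subject_id", "setting"], how="inner")
        hormone_rows = []
        for analyte in ANALYTES:
            for m in all_metrics:
                res = HormoneAssociationModel(
                    merged, analyte, m, standardize_metric=standardize_metric,
                    ci_method=ci_method).fit()
                hormone_rows.append({"analyte": analyte, "metric": m, **{
                    k: v for k, v in res.as_dict().items() if k not in ("outcome", "term")}})
        out["hormone_models"] = pd.DataFrame(hormone_rows)

    out["excluded"] = pd.DataFrame({"subject_id": excluded}) if excluded else pd.DataFrame(
        columns=["subject_id"])
    out["metrics_log"] = logm
    return out
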