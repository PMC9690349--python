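"""Inferential layer: transforms, paired setting comparison, PCA composite and
linear mixed-effects models.

Two model families are provided, both with a per-subject random intercept
fitted by REML (in a two-setting cross-over with at most a handful of rows
per subject, an unstructured random-effects covariance reduces to a single
intercept variance):

* :class:`SettingEffectModel` — log RQA metric ~ setting + age + sex,
  the within-subject contrast of mountainous vs. urban dynamics;
* :class:`HormoneAssociationModel` — log creatinine-adjusted hormone ~
  RQA metric (z-scored) + sample type + age.

Confidence intervals default to Wald intervals on a t reference with
containment-style degrees of freedom ``n_obs - n_groups - rank(X) + 1``;
z-based Wald intervals (estimate ± 1.96·SE) are available via
``ci_method="wald-z"``.  With ~14 subjects the t reference keeps the nominal
95% coverage that a z interval visibly loses.

TRE is never log-transformed: it is a signed slope, negative for the study's
series.  A signed-log option sign(x)·ln(1 + |x|/s) exists for completeness
but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_sensors import ANALYTES, ValidationError

__all__ = [
    "DEFAULT_LOG_METRICS",
    "ModelResult",
    "PairedTestResult",
    "PCAResult",
    "log_transform_metrics",
    "paired_t_test",
    "paired_tests_table",
    "pca_pc1",
    "prepare_hormones",
    "SettingEffectModel",
    "HormoneAssociationModel",
    "ModelConvergenceError",
]

#: metrics that are strictly positive and analysed on the log scale
DEFAULT_LOG_METRICS = ("REC", "DET", "LAM", "ENT", "DIV", "Lmean", "Vmean")


class ModelConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class ModelResult:
    """One fixed-effect row of a fitted mixed model (estimate on the log scale)."""

    outcome: str
    term: str
    estimate: float
    std_error: float
    p_value: float
    ci_lower: float
    ci_upper: float
    df: float
    n_obs: int
    n_groups: int

    def summary(self) -> str:
        return (
            f"{self.outcome} ~ ... : {self.term}\n"
            f"  estimate {self.estimate:.4g}  SE {self.std_error:.4g}  "
            f"p {self.p_value:.4g}  95% CI [{self.ci_lower:.4g}, {self.ci_upper:.4g}]  "
            f"(n_obs {self.n_obs}, subjects {self.n_groups})"
        )

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "term": self.term, "estimate": self.estimate,
            "std_error": self.std_error, "p_value": self.p_value,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        }


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test on per-subject differences (treatment − reference)."""

    metric: str
    n_pairs: int
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the correlation structure of standardized metrics."""

    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray          # (n_rows, n_components); column 0 is PC1
    loadings: pd.DataFrame      # metrics × components
    columns: tuple[str, ...]


def signed_log(x: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """sign(x)·ln(1 + |x|/scale): a log-like transform defined for negatives."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x) / scale)


def log_transform_metrics(
    metrics: pd.DataFrame,
    log_columns: Sequence[str] = DEFAULT_LOG_METRICS,
    passthrough: Sequence[str] = ("TRE",),
) -> pd.DataFrame:
    """Natural-log the strictly positive metric columns, pass TRE through.

    Raises naming the offending subject/setting/metric if a log-marked column
    is not strictly positive (degenerate recurrence structures surface here).
    """
    out = metrics.copy()
    for col in log_columns:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        bad = ~(vals > 0) | ~np.isfinite(vals)
        if bad.any():
            i = int(np.argmax(bad))
            subj = out.iloc[i].get("subject_id", f"row {i}")
            sett = out.iloc[i].get("setting", "")
            raise ValidationError(
                f"cannot log-transform {col} = {vals[i]!r} for {subj}/{sett}"
            )
        out[col] = np.log(vals)
    out.attrs["log_columns"] = [c for c in log_columns if c in out.columns]
    out.attrs["untransformed"] = [c for c in passthrough if c in out.columns]
    return out


def _pair_frame(
    data: pd.DataFrame, metric: str, treatment: str, reference: str
) -> pd.DataFrame:
    wide = data.pivot(index="subject_id", columns="setting", values=metric)
    return wide.dropna(subset=[treatment, reference])


def paired_t_test(
    data: pd.DataFrame,
    metric: str,
    treatment: str = "mountainous",
    reference: str = "urban",
    alpha: float = 0.05,
) -> PairedTestResult:
    """Paired t-test of ``metric`` between settings on complete pairs.

    ``data`` has one row per subject-setting with columns ``subject_id``,
    ``setting`` and the (typically log-transformed) metric.  Differences are
    treatment − reference.
    """
    wide = _pair_frame(data, metric, treatment, reference)
    d = (wide[treatment] - wide[reference]).to_numpy(dtype=float)
    n = d.size
    if n < 2:
        raise ValidationError(f"paired t-test needs >= 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"zero variance of paired differences for {metric}")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return PairedTestResult(
        metric=metric, n_pairs=n, mean_difference=float(mean), t_statistic=float(t),
        df=df, p_value=float(p), ci_lower=float(mean - crit * se),
        ci_upper=float(mean + crit * se),
    )


def paired_tests_table(data: pd.DataFrame, metrics: Iterable[str], **kwargs) -> pd.DataFrame:
    """Run :func:`paired_t_test` over several metrics; one row each."""
    rows = [paired_t_test(data, m, **kwargs).__dict__ for m in metrics]
    return pd.DataFrame(rows)


def pca_pc1(metrics: pd.DataFrame, columns: Sequence[str] | None = None) -> PCAResult:
    """PCA of the standardized metric columns; PC1 is the composite retained
    for the mixed models.

    Columns are z-scored (ddof=1) and the correlation matrix
    eigendecomposed.  PC1's sign is oriented so its loading on DET is
    positive (falling back to the largest-magnitude loading when DET is
    absent), making higher PC1 mean "more deterministic dynamics".
    """
    if columns is None:
        columns = [c for c in metrics.columns if c in DEFAULT_LOG_METRICS + ("TRE",)]
    columns = list(columns)
    x = metrics[columns].to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 rows and >= 2 metric columns")
    if np.isnan(x).any():
        raise ValidationError("PCA input contains missing values")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = columns[int(np.argmax(sd == 0))]
        raise ValidationError(f"constant column {bad!r}: cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    anchor = columns.index("DET") if "DET" in columns else int(np.argmax(np.abs(eigvecs[:, 0])))
    if eigvecs[anchor, 0] < 0:
        eigvecs[:, 0] = -eigvecs[:, 0]
    scores = z @ eigvecs
    return PCAResult(
        eigenvalues=eigvals,
        explained_variance_ratio=eigvals / eigvals.sum(),
        scores=scores,
        loadings=pd.DataFrame(eigvecs, index=columns,
                              columns=[f"PC{i+1}" for i in range(len(columns))]),
        columns=tuple(columns),
    )


def prepare_hormones(hormones: pd.DataFrame, analytes: Sequence[str] = ANALYTES) -> pd.DataFrame:
    """Impute below-LOD values to LOD/2, creatinine-adjust, natural-log.

    Adds a ``log_<analyte>_adj`` column per analyte.  Creatinine must be
    strictly positive (urine dilution correction divides by it).
    """
    out = hormones.copy()
    creat = out["creatinine"].to_numpy(dtype=float)
    if (creat <= 0).any() or np.isnan(creat).any():
        i = int(np.argmax((creat <= 0) | np.isnan(creat)))
        raise ValidationError(f"non-positive creatinine for {out.iloc[i]['subject_id']}")
    for a in analytes:
        vals = out[a].to_numpy(dtype=float).copy()
        below = out[f"{a}_below_lod"].astype(bool).to_numpy()
        lod = out[f"{a}_lod"].to_numpy(dtype=float)
        vals[below] = lod[below] / 2.0
        if (vals <= 0).any():
            i = int(np.argmax(vals <= 0))
            raise ValidationError(f"non-positive {a} after LOD/2 imputation "
                                  f"for {out.iloc[i]['subject_id']}")
        out[f"{a}_imputed"] = vals
        out[f"log_{a}_adj"] = np.log(vals / creat)
    return out


def _containment_df(n_obs: int, n_groups: int, rank_x: int) -> int:
    return max(n_obs - n_groups - rank_x + 1, 1)


def _fit_mixedlm(formula: str, data: pd.DataFrame, term: str, outcome: str,
                 ci_method: str, alpha: float = 0.05) -> ModelResult:
    groups = data["subject_id"]
    n_groups = groups.nunique()
    if n_groups < 3:
        raise ValidationError(f"need >= 3 subjects, got {n_groups}")
    model = smf.mixedlm(formula, data, groups=groups)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*boundary.*")
        warnings.filterwarnings("ignore", message=".*random effects covariance.*")
        for method in ("lbfgs", "cg", "powell"):  # boundary fits can stall one optimizer
            try:
                candidate = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                candidate = None
                continue
            if candidate.converged:
                fit = candidate
                break
    if fit is None:
        raise ModelConvergenceError(
            f"mixed model for {outcome} did not converge with any optimizer "
            f"(lbfgs, cg, powell); last gradient history: {getattr(candidate, 'hist', None)}"
        )
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fitted params {list(fit.params.index)}")
    est = float(fit.params[term])
    se = float(fit.bse[term])
    n_obs = int(len(data))
    rank_x = model.exog.shape[1]
    if ci_method == "wald-z":
        crit = sps.norm.ppf(1 - alpha / 2)
        p = 2 * sps.norm.sf(abs(est / se))
        df = float("inf")
    elif ci_method == "wald-t":
        df = _containment_df(n_obs, n_groups, rank_x)
        crit = sps.t.ppf(1 - alpha / 2, df)
        p = 2 * sps.t.sf(abs(est / se), df)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return ModelResult(
        outcome=outcome, term=term, estimate=est, std_error=se, p_value=float(p),
        ci_lower=est - crit * se, ci_upper=est + crit * se, df=float(df),
        n_obs=n_obs, n_groups=n_groups,
    )


class SettingEffectModel:
    """Mixed model of a (log) RQA metric on setting, adjusted for age and sex.

    ``data`` has one row per subject-setting with columns ``subject_id``,
    ``setting``, ``age``, ``sex`` and the metric (already transformed as
    desired — see :func:`log_transform_metrics`).  ``fit`` returns the
    mountainous-vs-urban fixed-effect row.
    """

    def __init__(self, data: pd.DataFrame, metric: str,
                 reference: str = "urban", ci_method: str = "wald-t") -> None:
        counts = data.groupby("subject_id")["setting"].count()
        if (counts > 2).any():
            raise ValidationError("a subject has more than two setting rows")
        self.data = data
        self.metric = metric
        self.reference = reference
        self.ci_method = ci_method

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, metric: str, **kwargs) -> "SettingEffectModel":
        return cls(data, metric, **kwargs)

    def fit(self) -> ModelResult:
        # a covariate constant across the cohort carries no information and
        # makes the design singular; drop it rather than fail.  Age is
        # centred and scaled for optimizer conditioning only — the setting
        # contrast is unchanged.
        data = self.data.copy()
        terms = [f"C(setting, Treatment('{self.reference}'))"]
        if data["age"].nunique() > 1:
            data["_age_c"] = (data["age"] - data["age"].mean()) / data["age"].std(ddof=1)
            terms.append("_age_c")
        if data["sex"].nunique() > 1:
            terms.append("C(sex)")
        formula = f"Q('{self.metric}') ~ " + " + ".join(terms)
        term = f"C(setting, Treatment('{self.reference}'))[T.mountainous]"
        return _fit_mixedlm(formula, data, term, outcome=self.metric,
                            ci_method=self.ci_method)


class HormoneAssociationModel:
    """Mixed model of a log creatinine-adjusted hormone on an RQA metric.

    ``data`` has one row per subject-setting-sample with columns
    ``subject_id``, ``sample_type``, ``age``, the prepared outcome
    ``log_<analyte>_adj`` (see :func:`prepare_hormones`) and the metric.
    The metric is z-scored across the analysis set by default, so the
    estimate is per SD of the metric; set ``standardize_metric=False`` to use
    the raw (log-)metric scale.
    """

    def __init__(self, data: pd.DataFrame, analyte: str, metric: str,
                 standardize_metric: bool = True, reference_sample: str = "night",
                 ci_method: str = "wald-t") -> None:
        self.analyte = analyte
        self.metric = metric
        self.standardize_metric = standardize_metric
        self.reference_sample = reference_sample
        self.ci_method = ci_method
        data = data.copy()
        x = data[metric].to_numpy(dtype=float)
        if standardize_metric:
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"constant metric {metric!r}: cannot standardize")
            data["_metric_x"] = (x - x.mean()) / sd
        else:
            data["_metric_x"] = x
        self.data = data

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, analyte: str, metric: str,
                       **kwargs) -> "HormoneAssociationModel":
        return cls(data, analyte, metric, **kwargs)

    def fit(self) -> ModelResult:
        outcome = f"log_{self.analyte}_adj"
        data = self.data.copy()
        terms = ["_metric_x", f"C(sample_type, Treatment('{self.reference_sample}'))"]
        if data["age"].nunique() > 1:
            data["_age_c"] = (data["age"] - data["age"].mean()) / data["age"].std(ddof=1)
            terms.append("_age_c")
        formula = f"{outcome} ~ " + " + ".join(terms)
        res = _fit_mixedlm(formula, data, "_metric_x", outcome=outcome,
                           ci_method=self.ci_method)
        return ModelResult(**{**res.__dict__, "term": self.metric})
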