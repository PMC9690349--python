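"""Synthetic cohort generator emulating the study's statistical structure.

Each subject-setting skin-temperature series is a diurnal sinusoid (peak in
the late evening, trough in the morning) plus AR(1) sensor/physiology noise,
with two kinds of superimposed structure whose balance differs by setting:

* laminar episodes — the value is held constant for an exponentially
  distributed duration (zero-order hold), the constancy that laminarity and
  vertical-line statistics respond to;
* perturbation pulses — short exponentially decaying temperature dips, the
  signature of moving between microenvironments (air conditioning, outdoor
  heat), which break diagonal lines.

The mountainous preset has a larger circadian amplitude, quieter noise,
longer and more frequent laminar episodes and fewer pulses than the urban
preset, so cohorts generated at the defaults show the mountainous > urban
ordering of determinism, laminarity, entropy and mean line lengths (and the
opposite sign for divergence) that motivates the paired design.

Hormone values follow the same linear-in-metric mixed structure the
inference layer fits: log(analyte/creatinine) = α + β·metric_z + b_subject +
γ·sample_type + ε, exponentiated back and multiplied by a simulated
creatinine, with a configurable limit of detection.

Every output is a pure function of (config, seed): one independent random
stream per (subject, setting, channel) is derived from the master seed, so
adding subjects never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_sensors import ANALYTES, TemperatureSeries, ValidationError, write_series, write_table
from . import rqa

__all__ = [
    "SettingDynamics",
    "HormoneParams",
    "SimulationConfig",
    "simulate_series",
    "simulate_hormones",
    "simulate_metric_cohort",
    "simulate_demographics",
    "make_fixture_cohort",
]

MINUTES_PER_DAY = 1440
_SETTING_CODE = {"urban": 0, "mountainous": 1}
_CH_NOISE, _CH_LAMINAR, _CH_PULSE, _CH_SUBJECT, _CH_HORMONE, _CH_INTERCEPT = range(6)


@dataclass(frozen=True)
class SettingDynamics:
    """Per-setting parameters of the temperature-series generator (°C, minutes)."""

    baseline: float = 35.0
    amplitude: float = 1.0
    acrophase_min: float = 1230.0      # peak time of day (20:30)
    ar_coefficient: float = 0.9
    innovation_sd: float = 0.05
    laminar_rate_per_day: float = 12.0
    laminar_mean_duration_min: float = 30.0
    pulse_rate_per_day: float = 6.0
    pulse_magnitude: float = -0.8
    pulse_duration_min: float = 6.0

    def __post_init__(self) -> None:
        if not -1 < self.ar_coefficient < 1:
            raise ValidationError("AR(1) coefficient must be in (-1, 1)")
        if self.innovation_sd < 0 or self.amplitude < 0:
            raise ValidationError("amplitude and innovation SD must be >= 0")
        if self.laminar_rate_per_day < 0 or self.pulse_rate_per_day < 0:
            raise ValidationError("event rates must be >= 0")
        if self.laminar_mean_duration_min <= 0 or self.pulse_duration_min <= 0:
            raise ValidationError("durations must be > 0")


#: defaults: the cooler setting is quieter, more laminar and more strongly cyclic
MOUNTAINOUS_DEFAULT = SettingDynamics(
    baseline=35.0, amplitude=1.1, ar_coefficient=0.9, innovation_sd=0.04,
    laminar_rate_per_day=18.0, laminar_mean_duration_min=45.0,
    pulse_rate_per_day=4.0, pulse_magnitude=-0.6,
)
URBAN_DEFAULT = SettingDynamics(
    baseline=35.1, amplitude=0.7, ar_coefficient=0.9, innovation_sd=0.12,
    laminar_rate_per_day=7.0, laminar_mean_duration_min=12.0,
    pulse_rate_per_day=28.0, pulse_magnitude=-1.0,
)


@dataclass(frozen=True)
class HormoneParams:
    """Ground truth of the hormone generator (log creatinine-adjusted scale)."""

    metric: str = "LAM"                # which (log) RQA metric drives hormones
    intercepts: dict = field(default_factory=lambda: {
        "leptin": 1.0, "adiponectin": 2.0, "cortisol": 3.0})
    slopes: dict = field(default_factory=lambda: {
        "leptin": 0.12, "adiponectin": 0.25, "cortisol": 0.07})
    sample_effects: dict = field(default_factory=lambda: {  # first_morning vs night
        "leptin": -0.2, "adiponectin": 0.0, "cortisol": 0.6})
    lods: dict = field(default_factory=lambda: {
        "leptin": 0.4, "adiponectin": 1.0, "cortisol": 2.5})
    subject_sd: float = 0.4
    residual_sd: float = 0.3
    creatinine_log_mean: float = 0.0   # creatinine ~ lognormal, g/L scale
    creatinine_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.subject_sd <= 0 or self.residual_sd <= 0 or self.creatinine_log_sd <= 0:
            raise ValidationError("SDs must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 14 subjects, one 24-h day at 1-minute sampling."""

    n_subjects: int = 14
    series_length: int = MINUTES_PER_DAY
    seed: int = 0
    urban: SettingDynamics = URBAN_DEFAULT
    mountainous: SettingDynamics = MOUNTAINOUS_DEFAULT
    hormones: HormoneParams = HormoneParams()

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.series_length < 2:
            raise ValidationError("need >= 1 subject and series length >= 2")

    def dynamics(self, setting: str) -> SettingDynamics:
        if setting not in _SETTING_CODE:
            raise ValidationError(f"unknown setting {setting!r}")
        return self.urban if setting == "urban" else self.mountainous


def _stream(cfg: SimulationConfig, subject_index: int, setting: str, channel: int) -> np.random.Generator:
    key = (subject_index, _SETTING_CODE.get(setting, 2), channel)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def simulate_series(cfg: SimulationConfig, subject_index: int, setting: str) -> TemperatureSeries:
    """One subject-setting temperature series, deterministic per (seed, subject, setting)."""
    dyn = cfg.dynamics(setting)
    L = cfg.series_length
    t = np.arange(L, dtype=np.float64)
    signal = dyn.baseline + dyn.amplitude * np.cos(
        2 * np.pi * (t - dyn.acrophase_min) / MINUTES_PER_DAY)

    rng_noise = _stream(cfg, subject_index, setting, _CH_NOISE)
    innov = rng_noise.normal(0.0, dyn.innovation_sd, size=L) if dyn.innovation_sd > 0 else np.zeros(L)
    signal = signal + lfilter([1.0], [1.0, -dyn.ar_coefficient], innov)

    rng_pulse = _stream(cfg, subject_index, setting, _CH_PULSE)
    n_pulses = rng_pulse.poisson(dyn.pulse_rate_per_day * L / MINUTES_PER_DAY)
    for _ in range(n_pulses):
        t0 = rng_pulse.integers(0, L)
        mag = dyn.pulse_magnitude * (0.5 + rng_pulse.random())
        tail = t[t0:] - t0
        signal[t0:] += mag * np.exp(-tail / dyn.pulse_duration_min)

    rng_lam = _stream(cfg, subject_index, setting, _CH_LAMINAR)
    n_ep = rng_lam.poisson(dyn.laminar_rate_per_day * L / MINUTES_PER_DAY)
    starts = np.sort(rng_lam.integers(0, L, size=n_ep))
    durations = rng_lam.exponential(dyn.laminar_mean_duration_min, size=n_ep)
    for s, dur in zip(starts, durations):
        e = min(L, int(s + max(dur, 1)))
        signal[s:e] = signal[s]  # zero-order hold

    return TemperatureSeries(
        subject_id=f"sub{subject_index + 1:02d}", setting=setting,
        timestamps=np.arange(L, dtype=np.int64), values=signal,
    )


def simulate_demographics(cfg: SimulationConfig) -> pd.DataFrame:
    """Ages, sexes and group assignment for the cohort (one row per subject)."""
    rows = []
    for i in range(cfg.n_subjects):
        rng = _stream(cfg, i, "urban", _CH_SUBJECT)
        rows.append({
            "subject_id": f"sub{i + 1:02d}",
            "group": "first_urban" if i < (cfg.n_subjects + 1) // 2 + 1 else "first_mountainous",
            "age": float(np.clip(np.round(rng.normal(42.0, 9.0)), 20, 60)),
            "sex": "male" if rng.random() < 0.21 else "female",
        })
    return pd.DataFrame(rows)


def simulate_hormones(cfg: SimulationConfig, metrics: pd.DataFrame) -> pd.DataFrame:
    """Two diurnal urine samples per subject-setting with hormone values driven
    linearly by an RQA metric.

    ``metrics`` has one row per subject-setting with columns ``subject_id``,
    ``setting`` and the driving metric named by ``cfg.hormones.metric``
    (log-scale metric values are the natural input).  The metric is z-scored
    across the table, so the planted slopes are per SD, matching what the
    inference layer estimates by default.
    """
    hp = cfg.hormones
    if hp.metric not in metrics.columns:
        raise ValidationError(f"metrics table lacks driving metric {hp.metric!r}")
    x = metrics[hp.metric].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    subject_ids = sorted(metrics["subject_id"].unique())
    b = {}
    for i, sid in enumerate(subject_ids):
        rng = _stream(cfg, i, "urban", _CH_INTERCEPT)
        b[sid] = rng.normal(0.0, hp.subject_sd)

    rows = []
    for (_, mrow), zval in zip(metrics.iterrows(), z):
        sid, setting = mrow["subject_id"], mrow["setting"]
        idx = subject_ids.index(sid)
        rng = _stream(cfg, idx, setting, _CH_HORMONE)
        for sample_type in ("first_morning", "night"):
            creat = float(np.exp(rng.normal(hp.creatinine_log_mean, hp.creatinine_log_sd)))
            row = {"subject_id": sid, "setting": setting, "sample_type": sample_type,
                   "creatinine": creat}
            for a in ANALYTES:
                mu = (hp.intercepts[a] + hp.slopes[a] * zval + b[sid]
                      + (hp.sample_effects[a] if sample_type == "first_morning" else 0.0))
                conc = float(np.exp(mu + rng.normal(0.0, hp.residual_sd)) * creat)
                below = conc < hp.lods[a]
                row[a] = min(conc, hp.lods[a]) if below else conc
                row[f"{a}_below_lod"] = below
                row[f"{a}_lod"] = hp.lods[a]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_metric_cohort(
    n_subjects: int = 14,
    beta_setting: float = 0.8,
    baseline: float = 1.9,
    subject_sd: float = 0.5,
    residual_sd: float = 0.5,
    metric: str = "Lmean",
    seed: int = 0,
) -> pd.DataFrame:
    """Directly plant a setting effect on a log-scale metric for recovery studies.

    Returns one row per subject-setting with ``subject_id``, ``setting``,
    ``age``, ``sex`` and the metric column already on the log scale:
    ``metric = baseline + beta·[mountainous] + b_subject + ε``.  Age and sex
    carry no true effect, mirroring their role as adjustment covariates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    rows = []
    for i in range(n_subjects):
        bi = rng.normal(0.0, subject_sd)
        age = float(np.clip(np.round(rng.normal(42.0, 9.0)), 20, 60))
        sex = "male" if rng.random() < 0.21 else "female"
        for setting in ("urban", "mountainous"):
            y = baseline + (beta_setting if setting == "mountainous" else 0.0) \
                + bi + rng.normal(0.0, residual_sd)
            rows.append({"subject_id": f"sub{i + 1:02d}", "setting": setting,
                         "age": age, "sex": sex, metric: y})
    return pd.DataFrame(rows)


def make_fixture_cohort(
    seed: int,
    outdir: str | Path,
    cfg: SimulationConfig | None = None,
) -> dict:
    """Write a complete miniature study to ``outdir``.

    Emits ``series/<subject>_<setting>.csv`` for every subject-setting,
    ``manifest.csv`` and ``hormones.csv`` in the dialects the readers expect.
    Hormones are driven by the log-laminarity actually computed from the
    generated series, so the full pipeline can recover the planted slope.
    Deterministic per seed.  Returns the paths written.
    """
    cfg = replace(cfg, seed=seed) if cfg is not None else SimulationConfig(seed=seed)
    outdir = Path(outdir)
    series_dir = outdir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)

    demo = simulate_demographics(cfg)
    manifest_rows, metric_rows = [], []
    for i in range(cfg.n_subjects):
        for setting in ("urban", "mountainous"):
            series = simulate_series(cfg, i, setting)
            fname = f"{series.subject_id}_{setting}.csv"
            write_series(series, series_dir / fname)
            d = demo.iloc[i]
            manifest_rows.append({
                "subject_id": series.subject_id, "group": d["group"], "age": d["age"],
                "sex": d["sex"], "setting": setting, "series_file": f"series/{fname}",
            })
            m = rqa.rqa_pipeline(series)
            metric_rows.append({"subject_id": series.subject_id, "setting": setting,
                                cfg.hormones.metric: float(np.log(getattr(m, cfg.hormones.metric)))})

    manifest = pd.DataFrame(manifest_rows)
    hormones = simulate_hormones(cfg, pd.DataFrame(metric_rows))
    write_table(manifest, outdir / "manifest.csv")
    write_table(hormones, outdir / "hormones.csv")
    return {"manifest": outdir / "manifest.csv", "hormones": outdir / "hormones.csv",
            "series_dir": series_dir, "n_series": cfg.n_subjects * 2}
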