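# Methods note

This note records what the package computes, the conventions it fixes where
the RQA literature is ambiguous, the default parameters and why they are the
defaults, what the synthetic generator does and does not emulate, and the
known limitations. Every number quoted here is produced by the test suite or
by `scripts/acceptance.py`; nothing is asserted beyond what those compute.

## 1. Model and procedure

### 1.1 Embedding and recurrence plot

A scalar series `x_1 … x_N` (one sample per minute) is embedded as

```
v_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ}),   i = 1 … n,   n = N − (m−1)τ
```

with dimension `m` and lag `τ`. The recurrence plot is the symmetric binary
matrix

```
R_ij = 1{ ‖v_i − v_j‖₂ ≤ r },    r = f · d̄,
```

where `d̄` is the mean of all n(n−1)/2 pairwise Euclidean distances and `f` is
the radius fraction. Because `r` is proportional to `d̄`, the matrix is
invariant under rescaling of the series (tested exactly with power-of-two
scale factors, where floating point introduces no rounding).

### 1.2 Line structure and metrics

Let the *line of identity* (LOI) be the main diagonal. Diagonal lines are
maximal runs of recurrent cells parallel to the LOI; vertical lines are
maximal runs within a column. With `P(l)` the diagonal line-length histogram
(lengths ≥ `lmin`), `p(l)` its normalisation, and `N_r` the number of
recurrent cells off the LOI:

| metric | definition |
| --- | --- |
| REC | `N_r / n²` |
| DET | (cells on diagonal lines of length ≥ lmin) / `N_r` |
| LAM | (cells on vertical lines of length ≥ lmin, LOI cells removed) / `N_r` |
| ENT | `−Σ_l p(l) · ln p(l)` |
| DIV | `1 / Lmax` (longest diagonal line) |
| TRE | OLS slope of `d_k = (recurrences on diagonal k) / (n − k)` on `k = 1 … n − 1 − border` |
| Lmean / Vmean | count-weighted mean diagonal / vertical line length |

### 1.3 Inclusion filter

A subject-setting record is eligible when fewer than 80% of its samples fall
below 30 °C (a sensor-off / detached-probe criterion, `threshold_c = 30.0`,
`exclusion_fraction = 0.80`). Eligibility is decided per subject with AND over
the two settings — the design is paired, so losing one setting loses the
subject. Filtering keeps only samples ≥ 30 °C; nothing is interpolated, and
every record's retained/dropped counts are reported.

### 1.4 Inference

All metrics except TRE are strictly positive in non-degenerate data and are
log-transformed before modelling; TRE is a signed slope near zero and enters
untransformed. Per metric:

* **paired t-test** of mountainous − urban within subject (closed form,
  cross-checked against `scipy.stats.ttest_rel` in the tests);
* **setting model** `log(metric) ~ setting + age + sex + (1 | subject)`;
* **hormone model**
  `log(analyte / creatinine) ~ z(metric) + sample_type + age + (1 | subject)`
  for leptin, adiponectin and cortisol, two urine samples (first morning,
  night) per subject-setting, values below the limit of detection imputed at
  LOD/2 before creatinine adjustment;
* **PC1**: first principal component of the z-scored log-metric panel
  (correlation-matrix eigendecomposition), sign-oriented so the DET loading
  is positive, appended to the panel and modelled like any metric.

Mixed models are fitted by REML with `statsmodels.MixedLM`; the random
structure is a single per-subject intercept (with one variance component and
a paired two-level design, an unstructured subject covariance reduces to
this). Covariates that are constant in a given dataset (e.g. an all-female
cohort) are dropped from the fixed effects rather than producing a singular
design.

## 2. Parameters, defaults, rationale

| parameter | default | why |
| --- | --- | --- |
| embedding dimension `m` | 2 | lowest dimension that separates value from velocity; diurnal temperature is a low-dimensional forced oscillation and higher `m` at N = 1440 thins the statistics |
| lag `τ` | 1 min | the sampling interval; with `m = 2` the embedded state is (value, next value) |
| radius fraction `f` | 0.10 | scale-free; yields sparse but line-rich plots on the default generator (cohort mean REC ≈ 0.066 at seed 1, acceptance script) |
| sensitivity radius | 0.01 | an order of magnitude tighter; exposed via `thermorqa rqa --sensitivity` so conclusions can be checked against radius choice |
| `lmin` | 2 | a "line" must be at least two consecutive recurrences; `lmin = 1` would make DET ≡ 1 |
| `border` | 2 | a 2-cell frame of the matrix is ignored for line counting, so runs truncated by the observation window do not masquerade as short lines |
| ENT log base | natural | nats; base only rescales ENT, comparisons are unaffected |
| inclusion threshold | 30 °C / 80% | below ~30 °C wrist skin temperature indicates a detached or uncovered sensor; a record mostly composed of such samples is unusable |
| CI method | `wald-t` | see section 4 |
| α | 0.05 | conventional two-sided level throughout |

Problem sizes are the package's own choice: the defaults target day-long
minute-resolution series (N ≈ 1440, so n ≈ 1439 embedded points and a
~2 × 10⁶-cell recurrence matrix, ≈ 0.1 s per series). Matrices up to
n ≈ 27 000 are supported through a tiled distance computation that stays
within 8 GB; the plotting layer refuses rasters above its pixel budget unless
downsampled (boolean max-pooling, a block is dark if any cell recurs).

## 3. Numerical conventions

These are the points where published RQA descriptions differ and a concrete
implementation must pick one; the reference oracle in `tests/_reference.py`
implements the same conventions naively and must agree exactly (matrices and
histograms bitwise; derived float metrics to 1e-12 relative, since the two
implementations sum in different orders).

* **LOI handling.** The LOI is excluded from `N_r` and from diagonal lines
  (otherwise DET is inflated by a trivial run of length n). It *does*
  participate in vertical runs — a laminar episode genuinely passes through
  the diagonal — but the LOI cells themselves are subtracted from the LAM
  numerator.
* **Mirror symmetry.** Diagonal lines are counted on both triangles (each
  upper-triangle run counts twice), consistent with `N_r` counting ordered
  pairs.
* **ENT sign.** Shannon entropy with the conventional minus sign,
  `−Σ p ln p ≥ 0`, equal to 0 when all diagonal lines share one length
  (verified analytically in the acceptance tests).
* **TRE convention.** Density per diagonal is normalised by the diagonal's
  own length `n − k`; the slope is an unweighted OLS fit over
  `k = 1 … n − 1 − border`, reported per sample step (per minute at default
  sampling).
* **Degenerate inputs.** A constant series has zero mean distance and no
  meaningful radius: `DegenerateSeriesError`. A plot with no off-LOI
  recurrences leaves DET/LAM undefined; no diagonal lines leave ENT, Lmean
  and DIV undefined; no vertical lines leave Vmean undefined. All are
  reported as NaN with a `UserWarning`, never silently as 0.
* **Ties at the radius.** The comparison is `≤ r`; distances exactly equal to
  the radius recur.
* **Determinism.** All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` with per-(subject, setting, channel) spawn
  keys, so any subseries of a cohort is reproducible independently of cohort
  size; CSV round-trips use `float_precision="round_trip"` and repeated runs
  are byte-identical.

## 4. Confidence intervals at n = 14

Wald intervals with z quantiles undercover with 14 subjects. The default is
therefore `wald-t`: `estimate ± t_{df, 0.975} · SE` with containment-style
degrees of freedom `df = n_obs − n_subjects − rank(X) + 1`. With the planted
effects used in the acceptance suite (setting effect β = 0.8 on log Lmean;
hormone slope β = 0.25 per SD of the metric), measured coverage over the 1000
replicate cohorts of `tests/test_acceptance.py` is 94.7% and 95.8%
respectively;
the acceptance script reports the same quantities for seed-derived replicate
sets, where batch-to-batch variation of about ±1 percentage point is visible.
`ci_method="wald-z"` restores the plain z interval; estimates, standard
errors and p-values are identical either way.

## 5. What the generator emulates — and what it does not

Each simulated day is

```
x_t = baseline + amplitude · cos(2π (t − acrophase)/1440) + AR(1) noise
      [+ zero-order-hold laminar episodes] [+ exponentially decaying pulses]
```

with independent streams per subject, setting and mechanism. The two presets
*are* the study conditions: the mountainous preset has larger circadian
amplitude (1.1 vs 0.7 °C), quieter noise (innovation SD 0.04 vs 0.12),
more and longer laminar episodes (18/day × 45 min vs 7/day × 12 min) and
fewer perturbation pulses (4/day vs 28/day). Demographics (ages ≈ N(42, 9²)
clipped to 20–60, 21% male, balanced cross-over order) and urinary hormones
(per-subject intercepts, planted metric slopes, sample-type offsets,
below-LOD flagging, lognormal creatinine) complete the cohort.

The generator emulates the *mechanisms that RQA is sensitive to*: periodic
revisiting (diagonal lines), laminar sticking (vertical lines), noise level
(recurrence sparsity) and transient excursions. It does not attempt
physiological realism beyond that — no weather or activity covariates, no
sleep architecture, no sensor drift or quantisation, no missing-data
mechanism, and hormone kinetics are reduced to a linear model on the log
scale. Presets were calibrated once to the qualitative regime expected of
such data (mean DET > 0.5, REC < 0.2, and the mountainous > urban ordering of
the line-structure metrics) and then frozen; the acceptance suite verifies
that the frozen defaults reproduce the expected sign pattern in every one of
its replicate cohorts.

## 6. Limitations

* RQA metric sampling distributions are not derived; all inference operates
  on the per-record metric values, and the CI calibration quoted above is for
  the planted-effect simulation models, not a guarantee for arbitrary data.
* With 14 subjects, mixed-model variance components are weakly identified;
  REML occasionally needs the implemented optimizer fallback ladder
  (L-BFGS → CG → Powell), and non-convergence is raised, not silenced.
* The radius rule (fraction of mean distance) is one convention among
  several (fixed radius, fixed recurrence rate); results at other conventions
  can be approximated via `radius_fraction` but are not parameterised
  directly.
* `m = 2, τ = 1` is a modelling default, not an estimate; the package does
  not implement false-nearest-neighbour or mutual-information selection of
  embedding parameters.
* The paired design drops subjects missing either setting; no imputation of
  missing records is attempted.
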