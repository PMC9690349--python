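"""Recurrence quantification analysis (RQA) of a scalar time series.

The series is embedded in a ``p``-dimensional phase space by taking lagged
copies (Takens delay embedding).  Two embedded points recur when their
Euclidean distance falls below a radius ``r`` set as a fraction of the mean
pairwise distance, which makes the recurrence matrix invariant to rescaling
of the measured values.  From the binary recurrence matrix, diagonal line
structures (repeated trajectory segments) and vertical line structures
(laminar, "stuck" states) yield the eight scalar descriptors:

========  ===========================================================
REC       recurrence rate: fraction of point pairs that recur
DET       determinism: fraction of recurrent points on diagonal lines
LAM       laminarity: fraction of recurrent points on vertical lines
ENT       Shannon entropy of the diagonal line-length distribution
DIV       divergence: 1 / Lmax (longest diagonal line)
TRE       trend: slope of recurrence density vs. distance from the LOI
Lmean     mean diagonal line length
Vmean     mean vertical line length
========  ===========================================================

Conventions (each recorded and configurable where noted): the line of
identity (LOI, the main diagonal) is excluded from recurrence counts and
from diagonal lines; cells within ``border`` points of the matrix edge are
ignored in all counts; the cell where a column crosses the LOI participates
in vertical runs (configurable); entropy uses the natural log by default.
Degenerate outputs (no recurrences, no lines) are reported as NaN with a
warning rather than as zeros, so downstream log transforms fail loudly.

The distance computation is tiled so the recurrence matrix of a multi-day
1-minute series (tens of thousands of points) fits comfortably in laptop
memory: only the boolean matrix and one row-block of distances are ever held.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .io_sensors import TemperatureSeries, ValidationError

__all__ = [
    "EmbeddingConfig",
    "RQAConfig",
    "RecurrencePlot",
    "LineDistributions",
    "RQAMetrics",
    "embed",
    "recurrence_plot",
    "extract_lines",
    "compute_metrics",
    "rqa_pipeline",
    "RecurrenceAnalysis",
    "RQAResults",
]

METRIC_NAMES = ("REC", "DET", "LAM", "ENT", "DIV", "TRE", "Lmean", "Vmean")

# above this many embedded points, distances are computed in row blocks
_TILE_THRESHOLD = 4000
_TILE_ROWS = 1024


class DegenerateSeriesError(ValidationError):
    """All embedded points coincide; no radius can be derived."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Takens delay-embedding parameters: dimension ``p`` and ``lag`` in samples."""

    dimension: int = 2
    lag: int = 1

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValidationError("embedding dimension must be >= 1")
        if self.lag < 1:
            raise ValidationError("lag must be >= 1")


@dataclass(frozen=True)
class RQAConfig:
    """Recurrence thresholding and line-counting parameters.

    radius_fraction
        Recurrence radius as a fraction of the mean distance between distinct
        pairs of embedded points (default 0.1; 0.01 for sensitivity runs).
    lmin
        Minimal diagonal/vertical line length counted (default 2).
    border
        Cells within this many points of the matrix edge are ignored.
    entropy_log_base
        "natural" (nats) or "base2" (bits) for ENT.
    loi_in_vertical
        Whether the LOI cell of a column participates in vertical runs.
    trend_exclude_far_fraction
        Fraction of the farthest diagonals excluded from the TRE regression
        (0 disables; some conventions drop the sparsest 10%).
    """

    radius_fraction: float = 0.1
    lmin: int = 2
    border: int = 2
    entropy_log_base: str = "natural"
    loi_in_vertical: bool = True
    trend_exclude_far_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius_fraction > 0:
            raise ValidationError("radius_fraction must be > 0")
        if self.lmin < 2:
            raise ValidationError("lmin must be >= 2")
        if self.border < 0:
            raise ValidationError("border must be >= 0")
        if self.entropy_log_base not in ("natural", "base2"):
            raise ValidationError("entropy_log_base must be 'natural' or 'base2'")
        if not 0 <= self.trend_exclude_far_fraction < 1:
            raise ValidationError("trend_exclude_far_fraction must be in [0, 1)")


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary recurrence matrix plus the radius actually used."""

    matrix: np.ndarray          # (n, n) bool, symmetric, unit diagonal
    radius: float               # absolute distance threshold
    mean_distance: float        # mean over the n(n-1)/2 distinct pairs
    radius_fraction: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class LineDistributions:
    """Line-length histograms extracted from a (border-trimmed) recurrence matrix.

    Diagonal runs are counted on both triangles (each upper-triangle run and
    its mirror), vertical runs once per column over the full matrix; by
    symmetry horizontal structures equal vertical ones and are not stored.
    """

    diagonal_hist: Mapping[int, int]
    vertical_hist: Mapping[int, int]
    lmax: int                       # longest diagonal run (0 if none)
    n_recurrent_offdiag: int        # off-LOI recurrent cells in the trimmed region
    n_loi_in_vertical_runs: int     # LOI cells inside counted vertical runs
    diag_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    # diag_counts[k-1] = recurrent cells on upper diagonal k of the trimmed matrix


@dataclass(frozen=True)
class RQAMetrics:
    """The eight scalar RQA descriptors for one series."""

    REC: float
    DET: float
    LAM: float
    ENT: float
    DIV: float
    TRE: float
    Lmean: float
    Vmean: float
    Lmax: int
    n_vectors: int

    def as_dict(self) -> dict[str, float]:
        return {
            "REC": self.REC, "DET": self.DET, "LAM": self.LAM, "ENT": self.ENT,
            "DIV": self.DIV, "TRE": self.TRE, "Lmean": self.Lmean, "Vmean": self.Vmean,
            "Lmax": self.Lmax, "n_vectors": self.n_vectors,
        }


def embed(values: np.ndarray | TemperatureSeries, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Build the delay-embedding matrix.

    Row ``i`` is ``(x_i, x_{i+lag}, ..., x_{i+(p-1)lag})``; only complete rows
    are kept, so the matrix has ``N - (p-1)*lag`` rows for a series of length
    ``N``.
    """
    if isinstance(values, TemperatureSeries):
        values = values.values
    x = np.asarray(values, dtype=np.float64)
    p, lag = cfg.dimension, cfg.lag
    n_min = (p - 1) * lag + 1
    if x.size < n_min:
        raise ValidationError(
            f"series of length {x.size} too short for dimension {p}, lag {lag}: "
            f"minimum length is {n_min}"
        )
    n_vectors = x.size - (p - 1) * lag
    idx = np.arange(n_vectors)[:, None] + lag * np.arange(p)[None, :]
    return x[idx]


def recurrence_plot(em: np.ndarray, cfg: RQAConfig = RQAConfig()) -> RecurrencePlot:
    """Threshold pairwise Euclidean distances into a binary recurrence matrix.

    The radius is ``radius_fraction`` times the mean distance over the
    ``n(n-1)/2`` distinct pairs.  Raises on a degenerate (all-identical)
    embedding, where no radius can be derived.
    """
    em = np.asarray(em, dtype=np.float64)
    if em.ndim == 1:
        em = em[:, None]
    n = em.shape[0]
    if n < 2:
        raise ValidationError("need at least two embedded points")
    if n <= _TILE_THRESHOLD:
        d = pdist(em)
        mean_distance = float(d.mean())
        if mean_distance == 0.0:
            raise DegenerateSeriesError("degenerate series: zero mean distance")
        radius = cfg.radius_fraction * mean_distance
        matrix = squareform(d <= radius)
        np.fill_diagonal(matrix, True)
        return RecurrencePlot(matrix=matrix, radius=radius, mean_distance=mean_distance,
                              radius_fraction=cfg.radius_fraction)
    # tiled path: two passes, never holding the full float distance matrix
    total = 0.0
    for i0 in range(0, n, _TILE_ROWS):
        i1 = min(i0 + _TILE_ROWS, n)
        d = cdist(em[i0:i1], em[i0:])
        mask = np.arange(i0, n)[None, :] > np.arange(i0, i1)[:, None]
        total += float(d[mask].sum())
    mean_distance = total / (n * (n - 1) / 2)
    if mean_distance == 0.0:
        raise DegenerateSeriesError("degenerate series: zero mean distance")
    radius = cfg.radius_fraction * mean_distance
    matrix = np.empty((n, n), dtype=bool)
    for i0 in range(0, n, _TILE_ROWS):
        i1 = min(i0 + _TILE_ROWS, n)
        matrix[i0:i1] = cdist(em[i0:i1], em) <= radius
    np.fill_diagonal(matrix, True)
    return RecurrencePlot(matrix=matrix, radius=radius, mean_distance=mean_distance,
                          radius_fraction=cfg.radius_fraction)


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-d boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64)
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return ends - starts


def _trimmed(matrix: np.ndarray, border: int) -> np.ndarray:
    """Zero the ``border``-wide frame; cells there are ignored in all counts."""
    if border == 0:
        return matrix.copy()
    m = matrix.copy()
    m[:border, :] = False
    m[-border:, :] = False
    m[:, :border] = False
    m[:, -border:] = False
    return m


def extract_lines(rp: RecurrencePlot, cfg: RQAConfig = RQAConfig()) -> LineDistributions:
    """Extract diagonal and vertical line-length histograms.

    Diagonal runs are maximal consecutive recurrences along lines parallel to
    (and excluding) the LOI; each upper-triangle run is counted together with
    its lower-triangle mirror.  Vertical runs are maximal consecutive
    recurrences within columns of the full (trimmed) matrix; runs shorter
    than ``lmin`` are discarded.
    """
    n = rp.n
    b = cfg.border
    m = _trimmed(rp.matrix, b)
    n_loi = max(n - 2 * b, 0)  # LOI cells surviving the trim
    n_offdiag = int(m.sum()) - n_loi

    diag_hist: dict[int, int] = {}
    diag_counts = np.zeros(max(n - 1, 0), dtype=np.int64)
    lmax = 0
    for k in range(1, n):
        dk = np.diagonal(m, k)
        diag_counts[k - 1] = int(dk.sum())
        if diag_counts[k - 1] == 0:
            continue
        for length in _run_lengths(dk):
            if length >= cfg.lmin:
                li = int(length)
                diag_hist[li] = diag_hist.get(li, 0) + 2  # run + its mirror
                if li > lmax:
                    lmax = li

    v = m if cfg.loi_in_vertical else m.copy()
    if not cfg.loi_in_vertical:
        np.fill_diagonal(v, False)
    vert_hist: dict[int, int] = {}
    n_loi_in_runs = 0
    for j in range(n):
        col = v[:, j]
        if not col.any():
            continue
        mi = col.astype(np.int8)
        d = np.diff(mi)
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mi[0]:
            starts = np.concatenate(([0], starts))
        if mi[-1]:
            ends = np.concatenate((ends, [n]))
        for s, e in zip(starts, ends):
            length = int(e - s)
            if length >= cfg.lmin:
                vert_hist[length] = vert_hist.get(length, 0) + 1
                if cfg.loi_in_vertical and s <= j < e:
                    n_loi_in_runs += 1

    return LineDistributions(
        diagonal_hist=diag_hist,
        vertical_hist=vert_hist,
        lmax=lmax,
        n_recurrent_offdiag=n_offdiag,
        n_loi_in_vertical_runs=n_loi_in_runs,
        diag_counts=diag_counts,
    )


def _hist_entropy(hist: Mapping[int, int], base: str) -> float:
    counts = np.array([hist[k] for k in sorted(hist)], dtype=np.float64)
    p = counts / counts.sum()
    log = np.log2 if base == "base2" else np.log
    return float(-(p * log(p)).sum())


def _hist_mean(hist: Mapping[int, int]) -> float:
    keys = sorted(hist)
    total = sum(hist[k] for k in keys)
    return sum(k * hist[k] for k in keys) / total


def compute_metrics(rp: RecurrencePlot, ld: LineDistributions, cfg: RQAConfig = RQAConfig()) -> RQAMetrics:
    """Turn a recurrence matrix and its line structures into the eight descriptors.

    REC normalises by ``n**2`` (n = number of embedded points); DET and LAM
    normalise by the off-LOI recurrent cells of the border-trimmed region, the
    same population their numerators are drawn from.  TRE is the least-squares
    slope of per-diagonal recurrence density ``d_k = (recurrences on diagonal
    k)/(n - k)`` against the distance ``k`` from the LOI, for ``k = 1 ..
    n - 1 - border``; density rather than raw count, since raw counts fall
    with diagonal length mechanically.
    """
    n = rp.n
    offdiag = ld.n_recurrent_offdiag
    rec = offdiag / n**2

    if offdiag == 0:
        warnings.warn("no off-diagonal recurrences; DET/LAM undefined", stacklevel=2)
        det = lam = float("nan")
    else:
        diag_cells = sum(k * v for k, v in ld.diagonal_hist.items())
        vert_cells = sum(k * v for k, v in ld.vertical_hist.items()) - ld.n_loi_in_vertical_runs
        det = diag_cells / offdiag
        lam = vert_cells / offdiag

    if ld.diagonal_hist:
        ent = _hist_entropy(ld.diagonal_hist, cfg.entropy_log_base)
        lmean = _hist_mean(ld.diagonal_hist)
    else:
        warnings.warn("no diagonal lines; ENT/Lmean/DIV undefined", stacklevel=2)
        ent = lmean = float("nan")
    div = 1.0 / ld.lmax if ld.lmax > 0 else float("nan")
    if ld.vertical_hist:
        vmean = _hist_mean(ld.vertical_hist)
    else:
        warnings.warn("no vertical lines; Vmean undefined", stacklevel=2)
        vmean = float("nan")

    k_max = n - 1 - cfg.border
    if k_max >= 2:
        k = np.arange(1, k_max + 1, dtype=np.float64)
        dens = ld.diag_counts[:k_max] / (n - k)
        if cfg.trend_exclude_far_fraction > 0:
            keep = int(np.ceil(k.size * (1 - cfg.trend_exclude_far_fraction)))
            k, dens = k[:keep], dens[:keep]
        tre = float(np.polyfit(k, dens, 1)[0])
    else:
        tre = float("nan")

    return RQAMetrics(REC=rec, DET=det, LAM=lam, ENT=ent, DIV=div, TRE=tre,
                      Lmean=lmean, Vmean=vmean, Lmax=ld.lmax, n_vectors=n)


def rqa_pipeline(
    series: TemperatureSeries | np.ndarray,
    embedding: EmbeddingConfig = EmbeddingConfig(),
    config: RQAConfig = RQAConfig(),
) -> RQAMetrics:
    """embed → recurrence_plot → extract_lines → compute_metrics, end to end."""
    em = embed(series, embedding)
    rp = recurrence_plot(em, config)
    ld = extract_lines(rp, config)
    return compute_metrics(rp, ld, config)


class RecurrenceAnalysis:
    """Recurrence quantification of one series, statsmodels-style.

    Examples
    --------
    >>> res = RecurrenceAnalysis(values).fit()
    >>> res.metrics.DET
    >>> print(res.summary())
    """

    def __init__(
        self,
        series: TemperatureSeries | np.ndarray,
        embedding: EmbeddingConfig = EmbeddingConfig(),
        config: RQAConfig = RQAConfig(),
    ) -> None:
        self.series = series
        self.embedding = embedding
        self.config = config

    def fit(self) -> "RQAResults":
        em = embed(self.series, self.embedding)
        rp = recurrence_plot(em, self.config)
        ld = extract_lines(rp, self.config)
        metrics = compute_metrics(rp, ld, self.config)
        return RQAResults(model=self, plot=rp, lines=ld, metrics=metrics)


@dataclass(frozen=True)
class RQAResults:
    """Fitted recurrence structure: matrix, line histograms and metrics."""

    model: RecurrenceAnalysis
    plot: RecurrencePlot
    lines: LineDistributions
    metrics: RQAMetrics

    def summary(self) -> str:
        e, q = self.model.embedding, self.model.config
        lines = [
            "Recurrence Quantification Analysis",
            "==================================",
            f"embedded points     {self.metrics.n_vectors}",
            f"dimension / lag     {e.dimension} / {e.lag}",
            f"radius              {self.plot.radius:.6g} "
            f"({q.radius_fraction:g} x mean distance {self.plot.mean_distance:.6g})",
            f"lmin / border       {q.lmin} / {q.border}",
            "----------------------------------",
        ]
        for name, val in self.metrics.as_dict().items():
            lines.append(f"{name:<8}{val:>14.6g}")
        return "\n".join(lines)
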