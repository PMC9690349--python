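"""Rendering of recurrence plots and diurnal temperature traces.

Recurrence matrices are rendered as square rasters, one dark pixel per
recurrent pair.  Large matrices are max-pooled before rendering (a block is
dark if any of its cells recurs) so sparse structure stays visible at
day-long sizes.  A plain-text PBM writer is provided for headless diffing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_sensors import TemperatureSeries, ValidationError
from .rqa import RecurrencePlot

__all__ = ["PlotSpec", "render_recurrence_plot", "render_series", "max_pool", "write_pbm"]


@dataclass(frozen=True)
class PlotSpec:
    """Where and how to render: output path, pooling factor, axis units."""

    path: str | Path
    downsample: int = 1
    axis_mode: str = "minutes"      # or "index"
    pixel_budget: int = 4096        # refuse larger rasters without pooling
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValidationError("downsample must be >= 1")
        if self.axis_mode not in ("minutes", "index"):
            raise ValidationError("axis_mode must be 'minutes' or 'index'")


def max_pool(matrix: np.ndarray, factor: int) -> np.ndarray:
    """Boolean max-pooling by ``factor`` (trailing partial blocks padded with False)."""
    if factor == 1:
        return matrix
    n = matrix.shape[0]
    m = -(-n // factor) * factor
    padded = np.zeros((m, m), dtype=bool)
    padded[:n, :n] = matrix
    return padded.reshape(m // factor, factor, m // factor, factor).any(axis=(1, 3))


def write_pbm(matrix: np.ndarray, path: str | Path) -> None:
    """Write a boolean matrix as plain-text PBM (P1), dark = recurrence."""
    n, m = matrix.shape
    with open(path, "w") as fh:
        fh.write(f"P1\n{m} {n}\n")
        for row in matrix:
            fh.write(" ".join("1" if v else "0" for v in row) + "\n")


def render_recurrence_plot(rp: RecurrencePlot, spec: PlotSpec) -> Path:
    """Render a recurrence matrix to PNG (or PBM if the path ends in .pbm)."""
    n = rp.n
    pooled_n = -(-n // spec.downsample)
    if pooled_n > spec.pixel_budget:
        factor = -(-n // spec.pixel_budget)
        raise ValidationError(
            f"matrix of size {n} exceeds the pixel budget {spec.pixel_budget}; "
            f"use downsample >= {factor}"
        )
    pooled = max_pool(rp.matrix, spec.downsample)
    path = Path(spec.path)
    if path.suffix.lower() == ".pbm":
        write_pbm(pooled, path)
        return path
    extent_max = n if spec.axis_mode == "minutes" else pooled.shape[0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(~pooled, cmap="gray", origin="lower", interpolation="none",
              extent=(0, extent_max, 0, extent_max))
    unit = "time (min)" if spec.axis_mode == "minutes" else "sample index"
    ax.set_xlabel(unit)
    ax.set_ylabel(unit)
    ax.set_title(f"Recurrence plot (r = {rp.radius:.3g})")
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    return path


def render_series(series: TemperatureSeries, spec: PlotSpec) -> Path:
    """Render a temperature trace to PNG."""
    path = Path(spec.path)
    fig, ax = plt.subplots(figsize=(8, 3))
    x = series.timestamps if spec.axis_mode == "minutes" else np.arange(len(series))
    ax.plot(x, series.values, lw=0.7, color="#1f4e79")
    ax.set_xlabel("time (min)" if spec.axis_mode == "minutes" else "sample index")
    ax.set_ylabel("skin temperature (°C)")
    ax.set_title(f"{series.subject_id} — {series.setting}")
    fig.tight_layout()
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    return path
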