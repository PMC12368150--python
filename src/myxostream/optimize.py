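"""Threshold selection by %FOV sweeps on calibration frames.

The three sweeps mirror how the cutoffs are chosen in practice, with the
human "sharp decline" judgment replaced by an explicit largest-forward-drop
rule so selection is deterministic and testable:

* **speed** — the mask should detect *that* cells move, not set a speed
  cutoff, so the chosen threshold is the largest grid value whose mean
  mask coverage still reaches a target fraction of the FOV (80% default);
* **alignment** — the %FOV-vs-threshold curve is swept and the threshold
  is placed right before its sharpest decline (the largest forward drop);
* **density** — two-sided: the lower bound sits just above the background
  drop of stream calibration frames, the upper bound just above the
  cell-population drop of aggregate-containing frames, each averaged over
  (typically three) calibration frames per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .masks import fov_percentage

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "sweep_speed", "sweep_alignment", "optimize_density"]


@dataclass
class SweepResult:
    """Outcome of one threshold sweep."""

    thresholds: np.ndarray
    fov_percent: np.ndarray  # (n_images, n_thresholds)
    chosen: float
    rule: str
    low_confidence: bool = False

    @property
    def mean_fov(self) -> np.ndarray:
        return self.fov_percent.mean(axis=0)


def _fov_curves(fields: list[np.ndarray], grid: np.ndarray) -> np.ndarray:
    """%FOV of the exceedance mask (value >= cutoff), per image and cutoff."""
    curves = np.empty((len(fields), len(grid)))
    for i, f in enumerate(fields):
        arr = np.asarray(f, dtype=np.float64)
        for j, t in enumerate(grid):
            curves[i, j] = fov_percentage(arr >= t)
    return curves


def sweep_speed(
    calibration_fields: list[np.ndarray],
    grid: np.ndarray | None = None,
    target_fov: float = 80.0,
) -> SweepResult:
    """Largest cutoff whose mean mask coverage still reaches ``target_fov``.

    ``calibration_fields`` are flow-magnitude rasters from stream-phase
    frame pairs. If no grid point reaches the target the grid minimum is
    chosen and a calibration warning logged.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 0.7 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=np.float64)
    if len(calibration_fields) == 0:
        raise ValueError("need at least one calibration field")
    curves = _fov_curves(calibration_fields, grid)
    mean = curves.mean(axis=0)
    passing = np.nonzero(mean >= target_fov)[0]
    if passing.size == 0:
        logger.warning(
            "no speed cutoff reaches %.0f%% FOV (max %.1f%%); falling back to grid minimum",
            target_fov,
            mean.max(),
        )
        return SweepResult(grid, curves, float(grid[0]), "target_fov_fallback", True)
    chosen = float(grid[passing[-1]])
    return SweepResult(grid, curves, chosen, f"largest cutoff with mean FOV >= {target_fov}%")


def _largest_drop_index(mean_curve: np.ndarray, min_drop: float = 1.0) -> int | None:
    """Index k of the largest forward drop curve[k] - curve[k+1]."""
    drops = mean_curve[:-1] - mean_curve[1:]
    if drops.size == 0 or drops.max() <= min_drop:
        return None
    return int(np.argmax(drops))


def sweep_alignment(
    calibration_fields: list[np.ndarray],
    grid: np.ndarray | None = None,
    min_drop: float = 1.0,
) -> SweepResult:
    """Threshold right before the sharpest decline of the %FOV curve.

    A flat curve (no drop above ``min_drop`` percentage points) yields the
    grid midpoint, flagged low-confidence.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 0.9 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=np.float64)
    if len(calibration_fields) == 0:
        raise ValueError("need at least one calibration field")
    curves = _fov_curves(calibration_fields, grid)
    mean = curves.mean(axis=0)
    k = _largest_drop_index(mean, min_drop)
    if k is None:
        logger.warning("alignment sweep: no drop > %.1f pp; using grid midpoint", min_drop)
        return SweepResult(grid, curves, float(grid[len(grid) // 2]), "flat_curve_fallback", True)
    # a decline that barely stands out from the typical step (e.g. a uniform
    # random field) gives a technically valid but untrustworthy choice
    drops = mean[:-1] - mean[1:]
    positive = drops[drops > 0]
    low_conf = bool(positive.size) and drops.max() < 2.0 * float(np.median(positive))
    return SweepResult(
        grid, curves, float(grid[k]), "value before largest forward drop", low_conf
    )


def _after_drop(field_raster: np.ndarray, grid: np.ndarray, min_drop: float) -> float | None:
    """Grid value right after the largest forward drop of one frame's curve."""
    curve = _fov_curves([field_raster], grid)[0]
    k = _largest_drop_index(curve, min_drop)
    return None if k is None else float(grid[k + 1])


def optimize_density(
    stream_fields: list[np.ndarray],
    aggregate_fields: list[np.ndarray],
    grid: np.ndarray | None = None,
    min_drop: float = 1.0,
) -> tuple[float, float]:
    """Two-sided density bounds from stream and aggregate calibration frames.

    Lower bound: per stream frame, the grid value just after the largest
    forward drop of the %FOV curve — the point where the (majority)
    background has dropped out and only cells remain. Upper bound: per
    aggregate frame, the same rule restricted to cutoffs above the lower
    bound — the point where the cell population has dropped out and only
    the aggregate's high-intensity core remains. Each bound is the mean of
    its per-frame values (three frames per replicate in the study design);
    replicates are optimized by calling this once per movie.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=np.float64)
    if len(stream_fields) == 0 or len(aggregate_fields) == 0:
        raise ValueError("need stream and aggregate calibration frames")

    lows = []
    for f in stream_fields:
        v = _after_drop(f, grid, min_drop)
        if v is not None:
            lows.append(v)
    if not lows:
        raise ValueError("no density drop found on stream calibration frames")
    density_min = float(np.mean(lows))

    highs = []
    upper_grid = grid[grid > density_min]
    if upper_grid.size < 2:
        raise ValueError("grid leaves no room above the lower density bound")
    for f in aggregate_fields:
        v = _after_drop(f, upper_grid, min_drop)
        if v is not None:
            highs.append(v)
    if not highs:
        raise ValueError("no density drop found on aggregate calibration frames")
    density_max = float(np.mean(highs))

    if density_min >= density_max:
        raise ValueError(
            f"density optimization failed: lower bound {density_min:.3f} >= "
            f"upper bound {density_max:.3f}"
        )
    return density_min, density_max
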