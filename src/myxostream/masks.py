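"""Stream-mask construction.

A stream is operationalized as a region that simultaneously clears three
per-pixel thresholds — moving (speed), nematically aligned (order
parameter), at moderate density (two-sided, excluding empty regions and
aggregates/clumps) — and does so persistently: in at least half of the
candidate masks of a 30-frame analysis window (the 15-of-30 rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import density_field, local_orientation, optical_flow_speed, order_parameter
from .persistence import AnalysisWindow, PersistenceStack, window_time_min

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "BinaryMask",
    "StreamMaskSeries",
    "threshold_mask",
    "candidate_mask",
    "persistence_filter",
    "required_count",
    "fov_percentage",
    "stream_series",
]


@dataclass
class ThresholdSet:
    """The six cutoffs defining the stream mask.

    speed_min is in optical-flow units (px/frame), align_min in order-
    parameter units, the density bounds in equalized-intensity units.
    ``persist_min_fraction`` of a window's candidate masks must contain a
    pixel for it to count as stream (0.5 of 30 frames = 15 min).
    """

    speed_min: float
    align_min: float
    density_min: float
    density_max: float
    persist_window_frames: int = 30
    persist_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.density_min >= self.density_max:
            raise ValueError("density_min must be < density_max")
        if not 0.0 <= self.align_min <= 1.0:
            raise ValueError("align_min must be in [0, 1]")
        if not 0.0 < self.persist_min_fraction <= 1.0:
            raise ValueError("persist_min_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BinaryMask:
    """A boolean raster with its role and timestamp."""

    pixels: np.ndarray
    kind: str = "stream"  # speed | alignment | density | candidate | stream
    timestamp_min: float = 0.0


@dataclass
class StreamMaskSeries:
    """Stream masks over analysis windows plus the %FOV trace."""

    masks: list[BinaryMask]
    fov_percent: np.ndarray
    timestamps_min: np.ndarray
    fov_percent_speed: np.ndarray = field(default=None)
    fov_percent_align: np.ndarray = field(default=None)
    fov_percent_density: np.ndarray = field(default=None)

    @property
    def peak_time_min(self) -> float:
        """Timestamp of maximum stream coverage (earliest window on ties)."""
        return float(self.timestamps_min[int(np.argmax(self.fov_percent))])


def threshold_mask(
    field_raster: np.ndarray,
    lo: float,
    hi: float = np.inf,
    kind: str = "stream",
    timestamp_min: float = 0.0,
) -> BinaryMask:
    """Pixels with ``lo <= value <= hi`` (bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    arr = np.asarray(field_raster, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("field contains non-finite values")
    return BinaryMask((arr >= lo) & (arr <= hi), kind=kind, timestamp_min=timestamp_min)


def candidate_mask(
    speed_mask: BinaryMask, align_mask: BinaryMask, density_mask: BinaryMask
) -> BinaryMask:
    """Pixelwise AND of the three feature masks."""
    shapes = {m.pixels.shape for m in (speed_mask, align_mask, density_mask)}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    return BinaryMask(
        speed_mask.pixels & align_mask.pixels & density_mask.pixels,
        kind="candidate",
        timestamp_min=speed_mask.timestamp_min,
    )


def required_count(n_masks: int, min_fraction: float) -> int:
    """Candidate masks a pixel must appear in: ceil(min_fraction * n)."""
    return math.ceil(min_fraction * n_masks)


def persistence_filter(
    candidates: list[BinaryMask] | np.ndarray,
    min_fraction: float = 0.5,
    timestamp_min: float = 0.0,
) -> BinaryMask:
    """Temporal persistence: keep pixels present in enough candidate masks.

    A pixel is stream if it is true in at least
    ``ceil(min_fraction * len(candidates))`` of the window's candidate
    masks — 15 for the half rule on a 30-mask window.
    """
    if isinstance(candidates, np.ndarray):
        stackarr = candidates.astype(bool)
    else:
        if len(candidates) == 0:
            raise ValueError("persistence filter needs at least one candidate mask")
        stackarr = np.stack([m.pixels for m in candidates])
    if stackarr.shape[0] == 0:
        raise ValueError("persistence filter needs at least one candidate mask")
    need = required_count(stackarr.shape[0], min_fraction)
    counts = stackarr.sum(axis=0)
    return BinaryMask(counts >= need, kind="stream", timestamp_min=timestamp_min)


def fov_percentage(mask: BinaryMask | np.ndarray) -> float:
    """Percentage of frame pixels that are true."""
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    return 100.0 * float(pixels.sum()) / pixels.size


def window_candidate_masks(
    persistence: PersistenceStack,
    window: AnalysisWindow,
    thresholds: ThresholdSet,
    flow_radius: int = 7,
    density_sigma_px: float = 10.0,
    orientation_window_px: int = 15,
    orientation_overlap: float = 0.70,
) -> tuple[list[BinaryMask], dict]:
    """Feature masks and their AND for each frame pair of one window.

    Candidate mask ``i`` combines the flow of persistence-frame pair
    ``(i, i+1)`` with the alignment and density of frame ``i``; a
    30-frame window therefore yields 29 candidate masks and the half rule
    requires ceil(0.5 * 29) = 15 of them.
    """
    frames = persistence.frames[window.start_frame : window.stop()]
    shape = frames.shape[1:]
    candidates: list[BinaryMask] = []
    fovs = {"speed": [], "align": [], "density": []}
    for i in range(len(frames) - 1):
        speed = optical_flow_speed(frames[i], frames[i + 1], radius=flow_radius)
        orient = local_orientation(frames[i], orientation_window_px, orientation_overlap)
        align = order_parameter(orient, out_shape=shape)
        rho = density_field(frames[i], sigma_px=density_sigma_px)
        m_speed = threshold_mask(speed.magnitude, thresholds.speed_min, kind="speed")
        m_align = threshold_mask(align.S, thresholds.align_min, kind="alignment")
        m_density = threshold_mask(
            rho.rho, thresholds.density_min, thresholds.density_max, kind="density"
        )
        fovs["speed"].append(fov_percentage(m_speed))
        fovs["align"].append(fov_percentage(m_align))
        fovs["density"].append(fov_percentage(m_density))
        candidates.append(candidate_mask(m_speed, m_align, m_density))
    return candidates, {k: float(np.mean(v)) for k, v in fovs.items()}


def stream_series(
    persistence: PersistenceStack,
    windows: list[AnalysisWindow],
    thresholds: ThresholdSet,
    **feature_kwargs,
) -> StreamMaskSeries:
    """Stream mask and %FOV for every analysis window.

    For each window: compute feature fields per persistence-frame pair,
    threshold them, AND, apply the temporal-persistence rule, and record
    the stream mask and coverage. Peak time resolves ties to the earliest
    window.
    """
    masks: list[BinaryMask] = []
    fov = np.empty(len(windows))
    times = np.empty(len(windows))
    fov_parts = {"speed": np.empty(len(windows)), "align": np.empty(len(windows)),
                 "density": np.empty(len(windows))}
    for w_idx, window in enumerate(windows):
        t_min = window_time_min(persistence, window)
        try:
            candidates, part_fov = window_candidate_masks(
                persistence, window, thresholds, **feature_kwargs
            )
            stream = persistence_filter(
                candidates, thresholds.persist_min_fraction, timestamp_min=t_min
            )
        except Exception as exc:  # annotate failures with the window time
            raise RuntimeError(f"stream mask failed at window T={t_min:.0f} min") from exc
        masks.append(stream)
        fov[w_idx] = fov_percentage(stream)
        times[w_idx] = t_min
        for k in fov_parts:
            fov_parts[k][w_idx] = part_fov[k]
    return StreamMaskSeries(
        masks=masks,
        fov_percent=fov,
        timestamps_min=times,
        fov_percent_speed=fov_parts["speed"],
        fov_percent_align=fov_parts["align"],
        fov_percent_density=fov_parts["density"],
    )
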