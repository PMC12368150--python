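"""Persistence images and analysis windows.

A persistence image is the pixelwise sum of a short symmetric moving window
of frames (default 5 at 1 frame/min): a moving cell leaves a streak whose
direction and length encode local motion and alignment. Persistence frames
are contrast-balanced by global histogram equalization and then grouped
into 30-frame analysis windows at a 5-minute stride for mask building.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .stack import ImageStack

__all__ = ["PersistenceStack", "AnalysisWindow", "persistence_stack", "equalize", "make_windows"]


@dataclass
class PersistenceStack:
    """Stack of persistence images.

    ``frames[k]`` sums input frames ``k .. k+window_len-1`` and is
    timestamped at the central input frame ``k + window_len//2``; edge
    frames where the symmetric window does not fit are dropped.
    """

    frames: np.ndarray
    window_len: int = 5
    equalized: bool = False
    frame_interval_min: float = 1.0
    um_per_px: float = 0.65

    def __len__(self) -> int:
        return self.frames.shape[0]

    def time_min(self, index: int) -> float:
        """Absolute time (min) of a persistence frame: its window center."""
        return (index + self.window_len // 2) * self.frame_interval_min


@dataclass
class AnalysisWindow:
    """A block of consecutive persistence frames analyzed as one timepoint."""

    start_frame: int
    length: int = 30
    stride_min: float = 5.0

    def stop(self) -> int:
        return self.start_frame + self.length


def persistence_stack(stack: ImageStack, window_len: int = 5) -> PersistenceStack:
    """Sum frames over a symmetric moving window of ``window_len`` frames.

    Sums are accumulated losslessly in float64 (32+ bits of integer
    precision for uint16 input); no equalization is applied here.
    """
    if window_len % 2 == 0:
        raise ValueError("window_len must be odd (symmetric window)")
    n = len(stack)
    if window_len > n:
        raise ValueError(
            f"window_len={window_len} exceeds stack length {n}; need at least {window_len} frames"
        )
    frames = stack.frames.astype(np.float64)
    # direct window sums (not a cumulative-sum trick): exact agreement with
    # a per-window summation at any intensity scale
    out = np.empty((n - window_len + 1, *frames.shape[1:]), dtype=np.float64)
    for k in range(out.shape[0]):
        out[k] = frames[k : k + window_len].sum(axis=0)
    return PersistenceStack(
        out,
        window_len=window_len,
        equalized=False,
        frame_interval_min=stack.frame_interval_min,
        um_per_px=stack.um_per_px,
    )


def equalize(persistence: PersistenceStack, nbins: int = 256) -> PersistenceStack:
    """Global per-frame histogram equalization to [0, 1].

    The mapping is the empirical CDF, hence monotone non-decreasing: pixel
    rank order is preserved up to ties. A constant frame maps to a single
    value without error.
    """
    out = np.empty(persistence.frames.shape, dtype=np.float64)
    for k, frame in enumerate(persistence.frames):
        if np.ptp(frame) == 0:
            out[k] = 1.0  # CDF of a constant image is 1 everywhere
        else:
            out[k] = exposure.equalize_hist(frame, nbins=nbins)
    return PersistenceStack(
        out,
        window_len=persistence.window_len,
        equalized=True,
        frame_interval_min=persistence.frame_interval_min,
        um_per_px=persistence.um_per_px,
    )


def make_windows(
    persistence: PersistenceStack, length: int = 30, stride_min: float = 5.0
) -> list[AnalysisWindow]:
    """Tile the persistence stack with analysis windows at a fixed stride.

    Windows start at frames ``0, s, 2s, ...`` where ``s`` is the stride
    converted to frames; only windows fully inside the stack are returned.
    """
    n = len(persistence)
    if length > n:
        raise ValueError(f"window length {length} exceeds persistence stack length {n}")
    stride_frames = max(1, int(round(stride_min / persistence.frame_interval_min)))
    starts = range(0, n - length + 1, stride_frames)
    return [AnalysisWindow(s, length, stride_min) for s in starts]


def window_time_min(persistence: PersistenceStack, window: AnalysisWindow) -> float:
    """Mid-window timestamp in minutes."""
    mid = window.start_frame + (window.length - 1) / 2.0
    return persistence.time_min(0) + mid * persistence.frame_interval_min
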