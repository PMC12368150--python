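"""Time-lapse image stack container and TIFF I/O.

An :class:`ImageStack` holds an ordered sequence of equal-shape grayscale
frames together with the two pieces of metadata every downstream stage
needs: the frame interval in minutes and the pixel size in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative, finite grayscale intensities.
    frame_interval_min : float
        Minutes between consecutive frames (default 1).
    um_per_px : float
        Microns per pixel.
    """

    frames: np.ndarray
    frame_interval_min: float = 1.0
    um_per_px: float = 0.65

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W); got shape {self.frames.shape}")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be >= 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def time_min(self, frame_index: int) -> float:
        """Absolute time T (minutes since movie start) of a frame."""
        return frame_index * self.frame_interval_min

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.frames)

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        frame_interval_min: float = 1.0,
        um_per_px: float = 0.65,
    ) -> "ImageStack":
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, frame_interval_min=frame_interval_min, um_per_px=um_per_px)
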