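"""Core data container for short-axis cine sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CineSequence"]


@dataclass
class CineSequence:
    """Ordered 2D intensity frames of one short-axis slice.

    frames : (F, H, W) float array; frame 0 is the end-diastolic
        reference.
    pixel_spacing : in-plane (x, y) spacing in mm.
    frame_interval : time between frames in ms.
    """

    frames: np.ndarray
    pixel_spacing: tuple = (1.0, 1.0)
    frame_interval: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (F, H, W)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        self.pixel_spacing = (float(self.pixel_spacing[0]),
                              float(self.pixel_spacing[1]))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]
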