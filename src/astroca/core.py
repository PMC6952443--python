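"""Shared containers for two-channel movies and coordinate conventions.

Coordinate convention used throughout the package: image axes are
(row, col) = (y, x); a displacement field ``u`` maps moving → fixed,
i.e. ``corrected(p) = moving(p + u(p))``.  All displacement amplitudes
are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TwoChannelMovie:
    """Registered functional + structural image stacks with metadata.

    Parameters
    ----------
    functional : ndarray, shape (n_frames, height, width)
        Ca²⁺-indicator channel (e.g. OGB).
    structural : ndarray, same shape
        Astrocyte-marker channel (e.g. SR101); anatomically static, used
        for motion estimation and ROI segmentation.
    frame_interval : float
        Seconds between frames.
    pixel_size : float or None
        Micrometres per pixel (optional, informational).
    """

    functional: np.ndarray
    structural: np.ndarray
    frame_interval: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.functional = np.asarray(self.functional, dtype=np.float64)
        self.structural = np.asarray(self.structural, dtype=np.float64)
        if self.functional.shape != self.structural.shape:
            raise ValueError(
                "functional and structural channels must share shape, got "
                f"{self.functional.shape} vs {self.structural.shape}"
            )
        if self.functional.ndim != 3:
            raise ValueError("channels must be 3-D (n_frames, height, width)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.functional.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.functional.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.functional.shape[1:]


@dataclass
class MotionField:
    """Per-frame motion estimates in the moving → fixed convention.

    ``rigid_shifts[t]`` is the (dy, dx) offset such that sampling frame
    ``t`` at ``p + shift`` aligns it with the reference; ``flow_fields[t]``
    is the dense residual displacement (2, H, W) applied after the rigid
    part.
    """

    rigid_shifts: np.ndarray            # (n_frames, 2)
    flow_fields: np.ndarray | None      # (n_frames, 2, H, W) or None
    reference_frame: int | str = "template"

    def __post_init__(self) -> None:
        self.rigid_shifts = np.asarray(self.rigid_shifts, dtype=np.float64)
        if self.rigid_shifts.ndim != 2 or self.rigid_shifts.shape[1] != 2:
            raise ValueError("rigid_shifts must have shape (n_frames, 2)")
        if self.flow_fields is not None:
            self.flow_fields = np.asarray(self.flow_fields, dtype=np.float64)
            if not np.all(np.isfinite(self.flow_fields)):
                raise ValueError("flow fields must be finite everywhere")
            if self.flow_fields.shape[0] != self.rigid_shifts.shape[0]:
                raise ValueError("flow_fields and rigid_shifts disagree on n_frames")

    @property
    def n_frames(self) -> int:
        return self.rigid_shifts.shape[0]

    def total_displacement(self, t: int, frame_shape: tuple[int, int]) -> np.ndarray:
        """Dense total displacement (2, H, W) for frame ``t``."""
        h, w = frame_shape
        d = np.zeros((2, h, w))
        d[0] += self.rigid_shifts[t, 0]
        d[1] += self.rigid_shifts[t, 1]
        if self.flow_fields is not None:
            d += self.flow_fields[t]
        return d
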