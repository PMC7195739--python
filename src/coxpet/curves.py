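"""Shared containers for framed PET data.

A dynamic PET acquisition is reconstructed into time frames; regional
radioactivity concentration averaged within each frame is the raw object
of kinetic analysis.  The containers here carry frame timing (minutes)
and concentration (kBq/mL) and are used by both the simulator and the
estimation code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve", "default_frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Start/end times of consecutive PET frames, in minutes.

    Frames must be ascending and non-overlapping, each end strictly after
    its start, and the first start non-negative.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or end.ndim != 1 or start.size != end.size:
            raise ValueError("frame_start and frame_end must be 1-D and the same length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if start[0] < 0:
            raise ValueError("first frame start must be >= 0")
        if np.any(end <= start):
            bad = int(np.argmax(end <= start))
            raise ValueError(f"frame {bad}: end ({end[bad]}) must exceed start ({start[bad]})")
        if np.any(start[1:] < end[:-1] - 1e-9):
            bad = int(np.argmax(start[1:] < end[:-1] - 1e-9)) + 1
            raise ValueError(f"frame {bad} overlaps or precedes frame {bad - 1}")

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints (minutes)."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations (minutes)."""
        return self.end - self.start

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])


def default_frame_schedule(total_minutes: float = 120.0) -> FrameSchedule:
    """A typical dynamic schedule for a short-lived tracer.

    Six 30-s frames, three 1-min, two 2-min, then 5-min frames out to
    ``total_minutes`` (90 or 120 min scans are the usual choices).
    """
    if total_minutes < 10:
        raise ValueError("total_minutes must be >= 10")
    durations = [0.5] * 6 + [1.0] * 3 + [2.0] * 2
    t = sum(durations)
    while t + 5.0 <= total_minutes + 1e-9:
        durations.append(5.0)
        t += 5.0
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(edges[:-1], edges[1:])


@dataclass
class TimeActivityCurve:
    """Regional radioactivity concentration per frame (kBq/mL).

    ``weights`` are optional per-frame fit weights; they are carried but
    the default graphical fits are unweighted.
    """

    region: str
    schedule: FrameSchedule
    values: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {self.values.size} does not match "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must match values in length")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")
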