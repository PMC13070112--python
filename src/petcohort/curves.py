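"""Frame schedules and framewise time-activity curves.

All kinetic equations in this package work in minutes; schedules are stored
in seconds (the unit scanners report) and converted once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DED_FRAME_DURATIONS_S",
    "PE2I_FRAME_DURATIONS_S",
    "ded_schedule",
    "pe2i_schedule",
]

SECONDS_PER_MINUTE = 60.0

#: 26-frame dynamic schedule, 55 min total (9x20 + 6x60 + 5x120 + 6x360 s).
DED_FRAME_DURATIONS_S = (20,) * 9 + (60,) * 6 + (120,) * 5 + (360,) * 6

#: 18-frame dynamic schedule, 55 min total (9x120 + 3x180 + 3x260 + 3x300 s).
PE2I_FRAME_DURATIONS_S = (120,) * 9 + (180,) * 3 + (260,) * 3 + (300,) * 3


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    start_s : array-like
        Frame start times in seconds.
    duration_s : array-like
        Frame durations in seconds; all strictly positive.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.shape != start.shape or start.size == 0:
            raise ValueError("start_s and duration_s must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be > 0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations_s, start_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations_s, dtype=float)
        start = start_s + np.concatenate([[0.0], np.cumsum(dur[:-1])])
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def total_s(self) -> float:
        return float(self.duration_s.sum())

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes, strictly increasing."""
        return (self.start_s + self.duration_s / 2.0) / SECONDS_PER_MINUTE

    @property
    def bounds_min(self) -> np.ndarray:
        """Frame boundary times in minutes (length n_frames + 1)."""
        return np.concatenate([self.start_s, [self.end_s[-1]]]) / SECONDS_PER_MINUTE

    def __eq__(self, other) -> bool:  # arrays defeat dataclass eq
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start_s, other.start_s) and np.array_equal(
            self.duration_s, other.duration_s
        )


def ded_schedule() -> FrameSchedule:
    """The 26-frame, 55-min irreversible-tracer schedule."""
    return FrameSchedule.from_durations(DED_FRAME_DURATIONS_S)


def pe2i_schedule() -> FrameSchedule:
    """The 18-frame, 55-min reversible-tracer schedule."""
    return FrameSchedule.from_durations(PE2I_FRAME_DURATIONS_S)


@dataclass
class TimeActivityCurve:
    """Decay-corrected radioactivity concentration per frame (kBq/ml)."""

    schedule: FrameSchedule
    activity: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        self.activity = act
        if act.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity length {act.size} != n_frames {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(act)):
            raise ValueError("activity must be finite")

    @property
    def times_min(self) -> np.ndarray:
        return self.schedule.midpoints_min

    def with_activity(self, activity, region: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.schedule, activity, self.region if region is None else region
        )
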