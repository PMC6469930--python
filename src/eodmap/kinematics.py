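"""Swim kinematics: speed, forward/backward classification, down states.

Pulse-type electric fish routinely swim backward (B-scans), so movement
direction cannot be read from the velocity vector alone: heading tracks the
body axis (head direction), and a frame counts as backward when the velocity
projects negatively onto that axis.  Turns are pooled with the swim state of
the same sign of that projection, so no separate turn detector is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .eod import EODRateSeries
from .errors import ValidationError

__all__ = [
    "TrackedTrajectory",
    "SwimSegmentLabels",
    "FORWARD",
    "BACKWARD",
    "QUIESCENT",
    "compute_speed",
    "classify_swim_direction",
    "detect_down_states",
]

log = logging.getLogger(__name__)

FORWARD = "forward"
BACKWARD = "backward"
QUIESCENT = "quiescent"


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


@dataclass
class TrackedTrajectory:
    """Head position (cm) and heading (rad, body axis) on a uniform video grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = self.times.size
        if not (self.x.size == self.y.size == self.heading.size == n):
            raise ValidationError("trajectory columns must have equal length")
        if n < 2:
            raise ValidationError("trajectory needs at least 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
            raise ValidationError("trajectory time grid must be uniform and increasing")
        finite = np.isfinite(self.heading)
        self.heading[finite] = wrap_angle(self.heading[finite])

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Trial duration = n_frames * dt (each frame owns one dt of time)."""
        return self.n_frames * self.dt

    def frame_of(self, t) -> np.ndarray:
        """Nearest video frame index for times ``t``; ties toward the earlier frame."""
        t = np.asarray(t, dtype=float)
        idx = np.ceil((t - self.times[0]) / self.dt - 0.5).astype(int)
        return np.clip(idx, 0, self.n_frames - 1)


@dataclass
class SwimSegmentLabels:
    """Per-frame swim-state label and speed."""

    labels: np.ndarray  # array of {forward, backward, quiescent}
    speed: np.ndarray  # cm/s

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.labels.shape != self.speed.shape:
            raise ValidationError("labels and speed must align")
        if np.any(self.speed < 0):
            raise ValidationError("speed must be non-negative")

    def time_in_state(self, state: str, dt: float) -> float:
        return float(np.count_nonzero(self.labels == state) * dt)


def _velocity(traj: TrackedTrajectory) -> tuple[np.ndarray, np.ndarray]:
    vx = np.gradient(traj.x, traj.dt)
    vy = np.gradient(traj.y, traj.dt)
    return vx, vy


def compute_speed(traj: TrackedTrajectory, smooth_window: int = 1) -> np.ndarray:
    """Swim speed (cm/s) per frame.

    Central-difference velocity magnitude (one-sided at the trial edges),
    optionally boxcar-smoothed over ``smooth_window`` frames.
    """
    vx, vy = _velocity(traj)
    speed = np.hypot(vx, vy)
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, k, mode="same")
    return speed


def classify_swim_direction(
    traj: TrackedTrajectory,
    speed_threshold: float = 1.0,
    smooth_window: int = 1,
) -> SwimSegmentLabels:
    """Label each frame forward / backward / quiescent.

    backward  : velocity . (cos h, sin h) < 0 and speed >= threshold
    forward   : projection >= 0 and speed >= threshold
    quiescent : speed below threshold, or heading missing (NaN; logged)
    """
    vx, vy = _velocity(traj)
    speed = compute_speed(traj, smooth_window=smooth_window)
    proj = vx * np.cos(traj.heading) + vy * np.sin(traj.heading)
    labels = np.full(traj.n_frames, FORWARD, dtype=object)
    labels[proj < 0] = BACKWARD
    labels[speed < speed_threshold] = QUIESCENT
    missing = ~np.isfinite(traj.heading)
    if np.any(missing):
        log.warning("classify_swim_direction: %d frames missing heading -> quiescent",
                    int(missing.sum()))
        labels[missing] = QUIESCENT
    return SwimSegmentLabels(labels=np.asarray(labels, dtype="U9"), speed=speed)


def detect_down_states(
    eod_rate: EODRateSeries,
    threshold: float = 50.0,
    min_duration: float = 1.0,
) -> list[tuple[float, float]]:
    """Maximal intervals (s) where the EOD rate stays below ``threshold`` Hz.

    Intervals shorter than ``min_duration`` are dropped.  Returned as
    half-open [start, stop) grid-time intervals; each sample owns one grid
    step of time, so a series entirely below threshold yields one interval
    spanning the whole series.
    """
    below = eod_rate.rate < threshold
    if not below.any():
        return []
    dt = eod_rate.dt
    if not math.isfinite(dt):
        raise ValidationError("down-state detection needs >= 2 grid samples")
    edges = np.diff(below.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(below.size)
    out = []
    for i0, i1 in zip(starts, stops):
        t0 = eod_rate.times[i0]
        t1 = eod_rate.times[0] + i1 * dt
        if t1 - t0 >= min_duration:
            out.append((float(t0), float(t1)))
    return out
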