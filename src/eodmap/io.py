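"""Trial readers and writers.

Interchange formats (all plain text, documented headers):

* ``trajectory.csv``  — columns ``t,x_cm,y_cm,heading_rad`` (s, cm, rad)
* ``eod_pulses.csv``  — column ``t`` (s)
* ``spikes_<unit>.csv`` — column ``t`` (s), one file per unit
* ``trace[_<tag>].csv`` — columns ``t,v`` for sampled voltage traces
* ``arena.json``      — tank, landmark polygons, pixel scale
* ``ground_truth.json`` — optional synthetic-trial sidecar
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaLayout
from .eod import EODPulseTrain, SampledTrace
from .errors import ValidationError
from .kinematics import TrackedTrajectory
from .triggered import SpikeTrain

__all__ = [
    "TrialBundle",
    "load_trial",
    "save_trial",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_pulses_csv",
    "write_pulses_csv",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_trace_csv",
    "write_trace_csv",
]

log = logging.getLogger(__name__)


@dataclass
class TrialBundle:
    """One trial: arena, trajectory, EOD train, per-unit spike trains."""

    trial_id: str
    arena: ArenaLayout
    trajectory: TrackedTrajectory
    eod: EODPulseTrain
    units: dict[str, SpikeTrain] = field(default_factory=dict)
    ground_truth: dict | None = None


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def write_trajectory_csv(path, traj: TrackedTrajectory) -> None:
    pd.DataFrame(
        {"t": traj.times, "x_cm": traj.x, "y_cm": traj.y, "heading_rad": traj.heading}
    ).to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path, max_gap_frames: int = 2) -> TrackedTrajectory:
    """Read a tracked trajectory; single-frame gaps are interpolated (logged),
    larger gaps are an error."""
    df = pd.read_csv(path)
    _require_columns(df, ["t", "x_cm", "y_cm", "heading_rad"], path)
    t = df["t"].to_numpy(float)
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 frames")
    if np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time column must be strictly increasing")
    dt = np.median(np.diff(t))
    n = int(round((t[-1] - t[0]) / dt)) + 1
    grid = t[0] + dt * np.arange(n)
    idx = np.round((t - t[0]) / dt).astype(int)
    if np.unique(idx).size != idx.size:
        raise ValidationError(f"{path}: duplicate frame times")
    if np.any(np.diff(idx) > max_gap_frames):
        raise ValidationError(f"{path}: gap longer than {max_gap_frames} frames")
    if idx.size == n:  # complete recording: pass the columns through
        return TrackedTrajectory(
            times=grid,
            x=df["x_cm"].to_numpy(float),
            y=df["y_cm"].to_numpy(float),
            heading=df["heading_rad"].to_numpy(float),
        )
    log.warning("%s: interpolated %d missing frame(s)", path, n - idx.size)
    x = np.interp(grid, t, df["x_cm"].to_numpy(float))
    y = np.interp(grid, t, df["y_cm"].to_numpy(float))
    # interpolate heading via its unit vector to respect wrapping
    hx = np.interp(grid, t, np.cos(df["heading_rad"].to_numpy(float)))
    hy = np.interp(grid, t, np.sin(df["heading_rad"].to_numpy(float)))
    return TrackedTrajectory(times=grid, x=x, y=y, heading=np.arctan2(hy, hx))


def write_pulses_csv(path, pulses: EODPulseTrain) -> None:
    pd.DataFrame({"t": pulses.pulse_times}).to_csv(path, index=False, float_format="%.12g")


def read_pulses_csv(path, trial_duration: float) -> EODPulseTrain:
    df = pd.read_csv(path)
    _require_columns(df, ["t"], path)
    return EODPulseTrain(pulse_times=df["t"].to_numpy(float), trial_duration=trial_duration)


def write_spikes_csv(path, spikes: SpikeTrain) -> None:
    pd.DataFrame({"t": spikes.spike_times}).to_csv(path, index=False, float_format="%.12g")


def read_spikes_csv(path, unit_id: str, trial_id: str, trial_duration: float) -> SpikeTrain:
    df = pd.read_csv(path)
    _require_columns(df, ["t"], path)
    t = df["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: spike times must be strictly increasing")
    return SpikeTrain(spike_times=t, unit_id=unit_id, trial_id=trial_id,
                      trial_duration=trial_duration)


def write_trace_csv(path, trace: SampledTrace) -> None:
    pd.DataFrame({"t": trace.times(), "v": trace.samples}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_trace_csv(path) -> SampledTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["t", "v"], path)
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValidationError(f"{path}: trace must be uniformly sampled")
    return SampledTrace(sample_rate=1.0 / dt[0], samples=df["v"].to_numpy(float), t0=t[0])


def save_trial(directory, bundle: TrialBundle) -> None:
    """Write a trial bundle as the standard CSV/JSON file set."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.arena.to_json(d / "arena.json")
    write_trajectory_csv(d / "trajectory.csv", bundle.trajectory)
    write_pulses_csv(d / "eod_pulses.csv", bundle.eod)
    for name, st in bundle.units.items():
        write_spikes_csv(d / f"spikes_{name}.csv", st)
    if bundle.ground_truth is not None:
        with open(d / "ground_truth.json", "w") as fh:
            json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def load_trial(directory, trial_id: str | None = None) -> TrialBundle:
    """Load a trial directory written by :func:`save_trial` (or assembled by
    hand in the same dialect).  Every ``spikes_*.csv`` becomes a unit."""
    d = Path(directory)
    trial_id = trial_id or d.name
    arena = ArenaLayout.from_json(d / "arena.json")
    traj = read_trajectory_csv(d / "trajectory.csv")
    eod = read_pulses_csv(d / "eod_pulses.csv", trial_duration=traj.duration)
    units = {}
    for p in sorted(d.glob("spikes_*.csv")):
        name = p.stem.removeprefix("spikes_")
        units[name] = read_spikes_csv(p, unit_id=name, trial_id=trial_id,
                                      trial_duration=traj.duration)
    gt_path = d / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return TrialBundle(trial_id=trial_id, arena=arena, trajectory=traj,
                       eod=eod, units=units, ground_truth=ground_truth)
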