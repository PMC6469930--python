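"""Electric-organ-discharge (EOD) processing.

Each EOD pulse is one electrosensory sampling event.  This module derives
the instantaneous EOD rate from pulse times, blanks EOD artifacts out of
extracellular voltage traces, and provides the threshold-crossing counter
used to bound the spike loss the blanking causes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ValidationError

__all__ = [
    "EODPulseTrain",
    "EODRateSeries",
    "SampledTrace",
    "instantaneous_eod_rate",
    "blank_eod_artifacts",
    "count_threshold_crossings",
    "detect_pulses",
]


@dataclass
class EODPulseTrain:
    """Strictly increasing EOD pulse times (s) within one trial."""

    pulse_times: np.ndarray
    trial_duration: float

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_times.ndim != 1:
            raise ValidationError("pulse_times must be 1-D")
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValidationError("pulse_times must be strictly increasing")
        if self.pulse_times.size and (
            self.pulse_times[0] < 0 or self.pulse_times[-1] >= self.trial_duration
        ):
            raise ValidationError("pulse times must lie in [0, trial_duration)")

    def __len__(self) -> int:
        return self.pulse_times.size


@dataclass
class EODRateSeries:
    """Instantaneous EOD rate (Hz) on a uniform time grid."""

    times: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.shape != self.rate.shape:
            raise ValidationError("times and rate must have the same shape")
        if np.any(self.rate < 0):
            raise ValidationError("rate must be non-negative")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else math.nan


@dataclass
class SampledTrace:
    """A uniformly sampled voltage trace (arbitrary units)."""

    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


def instantaneous_eod_rate(
    pulses: EODPulseTrain,
    grid_dt: float = 1.0 / 15.0,
    grid: np.ndarray | None = None,
    smooth_sigma: float | None = None,
) -> EODRateSeries:
    """Instantaneous EOD rate sampled on a uniform grid.

    The rate at grid time ``t`` is the reciprocal of the inter-pulse
    interval containing ``t`` (a step function); before the first and
    after the last pulse the first/last interval's rate is extrapolated.

    Parameters
    ----------
    pulses : EODPulseTrain
    grid_dt : float
        Grid step (s); the default shares the 15 Hz video time base.
    grid : ndarray, optional
        Explicit uniform grid (e.g. the trajectory's ``times``); overrides
        ``grid_dt``.
    smooth_sigma : float, optional
        If given, Gaussian-smooth the sampled rate with this sigma in
        seconds (display convenience; off by default).
    """
    t = pulses.pulse_times
    if t.size < 2:
        raise ValidationError("instantaneous rate undefined for < 2 pulses")
    if grid is None:
        n = int(math.floor(pulses.trial_duration / grid_dt))
        grid = np.arange(n) * grid_dt
    else:
        grid = np.asarray(grid, dtype=float)
    isi_rate = 1.0 / np.diff(t)
    # interval index containing each grid point, clipped for extrapolation
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, isi_rate.size - 1)
    rate = isi_rate[idx]
    if smooth_sigma is not None and grid.size > 1:
        rate = gaussian_filter1d(rate, smooth_sigma / (grid[1] - grid[0]))
    return EODRateSeries(times=grid, rate=rate)


def blank_eod_artifacts(
    trace: SampledTrace, pulses: EODPulseTrain, half_window: float = 2.8e-3
) -> SampledTrace:
    """Zero the trace in a +/- ``half_window`` window around every EOD pulse.

    Samples with |t - pulse| <= half_window (union over pulses, overlapping
    windows merge) are set to exactly 0; all other samples are unchanged.
    """
    if half_window <= 0:
        raise ValidationError("half_window must be positive")
    out = trace.samples.copy()
    fs, t0, n = trace.sample_rate, trace.t0, out.size
    eps = 1e-9  # absorb float rounding at the closed window edges
    for p in pulses.pulse_times:
        lo = int(math.ceil((p - half_window - t0) * fs - eps))
        hi = int(math.floor((p + half_window - t0) * fs + eps))
        if hi < 0 or lo >= n:
            continue
        out[max(lo, 0) : min(hi, n - 1) + 1] = 0.0
    return SampledTrace(sample_rate=fs, samples=out, t0=t0)


def count_threshold_crossings(trace: SampledTrace, threshold: float) -> int:
    """Number of upward threshold crossings (sample i-1 < thr <= sample i).

    Counting crossings on the raw versus the blanked trace bounds the
    fraction of spikes lost to artifact blanking: (raw - blanked) / raw.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    v = trace.samples
    return int(np.count_nonzero((v[:-1] < threshold) & (v[1:] >= threshold)))


def detect_pulses(
    trace: SampledTrace, threshold: float, refractory: float = 5e-3
) -> EODPulseTrain:
    """Simple threshold + refractory EOD pulse detector on a raw tank-electrode
    trace.  Pulse time = first sample of each upward crossing; crossings within
    ``refractory`` seconds of the previous accepted pulse are ignored.
    """
    v = trace.samples
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = trace.t0 + idx / trace.sample_rate
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] > refractory:
            kept.append(float(t))
    duration = trace.t0 + v.size / trace.sample_rate
    return EODPulseTrain(pulse_times=np.asarray(kept), trial_duration=duration)
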