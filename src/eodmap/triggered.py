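"""Spike-triggered averages of behavioral covariates with circular-shift nulls.

stEODr / stSpeed / stSmpD: the EOD rate, swim speed and sampling density
(EOD pulses per cm = rate/speed) averaged in a +/-4 s window around every
spike of a unit.  Significance is assessed against surrogate trains obtained
by circularly shifting the whole spike train by a random time of at least
30 s, which preserves the inter-spike-interval structure while decoupling
spikes from behavior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientSpikesError, ValidationError

__all__ = [
    "SpikeTrain",
    "TriggeredAverage",
    "NullEnsemble",
    "PeakDipTiming",
    "spike_triggered_average",
    "st_sampling_density",
    "circular_shift_null",
    "null_triggered_averages",
    "test_mean_elevation",
    "test_peak",
    "peak_dip_timing",
    "sign_test",
    "linear_r2",
]

log = logging.getLogger(__name__)

MIN_SPIKES = 10  # units must fire more than this many spikes to be analysed


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit in one trial."""

    spike_times: np.ndarray
    unit_id: str = "unit"
    trial_id: str = "trial"
    trial_duration: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if self.trial_duration is not None and self.spike_times.size:
            if self.spike_times[0] < 0 or self.spike_times[-1] >= self.trial_duration:
                raise ValidationError("spike times must lie in [0, trial_duration)")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class TriggeredAverage:
    """Mean +/- SEM of a covariate around spike times, per-spike snippets kept."""

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_spikes: int
    per_spike: np.ndarray | None = None  # (n_spikes, n_lags)
    variable: str = ""

    def window_means(self) -> np.ndarray:
        """Per-spike mean of the covariate over the whole window."""
        if self.per_spike is None:
            raise ValidationError("per-spike snippets were not retained")
        return self.per_spike.mean(axis=1)


@dataclass
class NullEnsemble:
    """Circularly shifted surrogate spike trains and their triggered averages."""

    shift_values: np.ndarray
    surrogates: list[SpikeTrain]
    n_shifts: int
    null_averages: list[TriggeredAverage] = field(default_factory=list)
    null_window_means: list[np.ndarray] = field(default_factory=list)


@dataclass
class PeakDipTiming:
    """Per-spike timing of the extremum of a covariate snippet."""

    times: np.ndarray  # s, one per spike with a defined extremum
    median: float
    n_excluded: int  # spikes with no interior local minimum (dip mode)
    sign_test_p: float
    mode: str = "peak"


def _uniform_dt(times: np.ndarray) -> float:
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("covariate series must be on a uniform grid")
    return float(dt[0])


def spike_triggered_average(
    times: np.ndarray,
    values: np.ndarray,
    spikes: SpikeTrain,
    half_window: float = 4.0,
    min_spikes: int = MIN_SPIKES,
    keep_traces: bool = True,
    variable: str = "",
) -> TriggeredAverage:
    """Average a uniformly sampled covariate in +/-``half_window`` s around spikes.

    Spikes whose window crosses the trial edges are dropped (behavioral
    series are not circular).  Raises :class:`InsufficientSpikesError` when
    fewer than ``min_spikes`` eligible spikes remain.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValidationError("times and values must align")
    dt = _uniform_dt(times)
    nlag = int(round(half_window / dt))
    lags = np.arange(-nlag, nlag + 1) * dt
    idx = np.round((spikes.spike_times - times[0]) / dt).astype(int)
    ok = (idx - nlag >= 0) & (idx + nlag < times.size)
    idx = idx[ok]
    if idx.size < min_spikes:
        raise InsufficientSpikesError(
            f"unit {spikes.unit_id}: {idx.size} eligible spikes < {min_spikes}"
        )
    snippets = values[idx[:, None] + np.arange(-nlag, nlag + 1)[None, :]]
    mean = snippets.mean(axis=0)
    sem = (
        snippets.std(axis=0, ddof=1) / np.sqrt(snippets.shape[0])
        if snippets.shape[0] > 1
        else np.zeros_like(mean)
    )
    return TriggeredAverage(
        lags=lags,
        mean=mean,
        sem=sem,
        n_spikes=idx.size,
        per_spike=snippets if keep_traces else None,
        variable=variable,
    )


def st_sampling_density(
    steodr: TriggeredAverage,
    stspeed: TriggeredAverage,
    speed_floor: float = 0.5,
) -> TriggeredAverage:
    """Spike-triggered sampling density (pulses/cm) = per-spike stEODr / stSpeed.

    The quotient is taken per spike and per lag, then averaged — not the
    quotient of the mean traces.  Speeds are floored at ``speed_floor`` cm/s
    before dividing to prevent blow-ups at quiescence edges; spikes whose
    speed snippet is identically zero are excluded (and logged).
    """
    if steodr.per_spike is None or stspeed.per_spike is None:
        raise ValidationError("sampling density needs per-spike snippets")
    if steodr.per_spike.shape != stspeed.per_spike.shape or not np.allclose(
        steodr.lags, stspeed.lags
    ):
        raise ValidationError("stEODr and stSpeed must share spikes and lag grid")
    keep = ~np.all(stspeed.per_spike == 0, axis=1)
    if not keep.all():
        log.info("st_sampling_density: excluded %d all-zero-speed spikes",
                 int((~keep).sum()))
    if keep.sum() == 0:
        raise InsufficientSpikesError("no spikes with nonzero speed snippets")
    q = steodr.per_spike[keep] / np.maximum(stspeed.per_spike[keep], speed_floor)
    mean = q.mean(axis=0)
    sem = q.std(axis=0, ddof=1) / np.sqrt(q.shape[0]) if q.shape[0] > 1 else np.zeros_like(mean)
    return TriggeredAverage(
        lags=steodr.lags.copy(),
        mean=mean,
        sem=sem,
        n_spikes=int(keep.sum()),
        per_spike=q,
        variable="smpd",
    )


def circular_shift_null(
    spikes: SpikeTrain,
    trial_duration: float,
    n_shifts: int = 100,
    min_shift: float = 30.0,
    rng: np.random.Generator | None = None,
) -> NullEnsemble:
    """Surrogate trains: the whole train circularly shifted by a random time
    drawn uniformly from [min_shift, trial_duration - min_shift].

    Each surrogate preserves the spike count and the circular ISI multiset.
    """
    if trial_duration <= 2 * min_shift:
        raise ValidationError(
            f"trial ({trial_duration:.1f} s) too short for min_shift={min_shift} s"
        )
    rng = rng or np.random.default_rng()
    shifts = rng.uniform(min_shift, trial_duration - min_shift, size=n_shifts)
    surrogates = []
    for s in shifts:
        t = np.sort(np.mod(spikes.spike_times + s, trial_duration))
        surrogates.append(
            SpikeTrain(
                spike_times=t,
                unit_id=spikes.unit_id,
                trial_id=spikes.trial_id,
                trial_duration=trial_duration,
            )
        )
    return NullEnsemble(shift_values=shifts, surrogates=surrogates, n_shifts=n_shifts)


def null_triggered_averages(
    times: np.ndarray,
    values: np.ndarray,
    null: NullEnsemble,
    half_window: float = 4.0,
    min_spikes: int = 1,
    variable: str = "",
) -> NullEnsemble:
    """Compute triggered averages for every surrogate in the ensemble.

    Fills ``null_averages`` (mean traces, snippets dropped to save memory)
    and ``null_window_means`` (per-spike window means, the pooled null for
    the mean-elevation test).  Returns the same ensemble.
    """
    null.null_averages = []
    null.null_window_means = []
    for surr in null.surrogates:
        ta = spike_triggered_average(
            times, values, surr, half_window=half_window,
            min_spikes=min_spikes, keep_traces=True, variable=variable,
        )
        null.null_window_means.append(ta.window_means())
        ta.per_spike = None
        null.null_averages.append(ta)
    return null


@dataclass
class MeanElevationResult:
    statistic: float  # Kruskal-Wallis H
    p_value: float
    observed_mean: float
    null_mean: float
    p_permutation: float  # group-level: observed mean vs surrogate means


def test_mean_elevation(observed: TriggeredAverage, null: NullEnsemble) -> MeanElevationResult:
    """Is the covariate elevated around spikes relative to shifted spikes?

    Kruskal-Wallis between the observed per-spike window means and the
    pooled per-spike window means of all surrogates.  A group-level
    permutation p (rank of the observed grand mean among the surrogate
    grand means) is reported alongside; it respects the exchangeability
    of whole trains rather than of individual (autocorrelated) spikes.
    """
    obs = observed.window_means()
    if not null.null_window_means:
        raise ValidationError("null ensemble has no window means; run "
                              "null_triggered_averages first")
    pooled = np.concatenate(null.null_window_means)
    if np.ptp(np.concatenate([obs, pooled])) == 0:
        warnings.warn("mean-elevation test degenerate: all values tied; p = 1")
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(obs, pooled)
    surr_means = np.array([m.mean() for m in null.null_window_means])
    # one-sided permutation p with the +1 correction
    p_perm = (1 + np.count_nonzero(surr_means >= obs.mean())) / (1 + surr_means.size)
    return MeanElevationResult(
        statistic=float(h),
        p_value=float(p),
        observed_mean=float(obs.mean()),
        null_mean=float(pooled.mean()),
        p_permutation=float(p_perm),
    )


@dataclass
class PeakTestResult:
    peak_lag: float
    statistic: float
    p_value: float
    n: int
    which: str


def test_peak(observed: TriggeredAverage, which: str = "peak") -> PeakTestResult:
    """Wilcoxon sign-rank test of the extremum of the mean triggered average.

    The lag of the peak (dip) of the mean trace is located first; each
    spike's covariate value at that lag is then compared with that spike's
    whole-window mean (one-sided: greater for peaks, less for dips).
    """
    if observed.per_spike is None:
        raise ValidationError("test_peak needs per-spike snippets")
    if which not in ("peak", "dip"):
        raise ValidationError("which must be 'peak' or 'dip'")
    i = int(np.argmax(observed.mean) if which == "peak" else np.argmin(observed.mean))
    at_peak = observed.per_spike[:, i]
    d = at_peak - observed.window_means()
    if d.size < MIN_SPIKES:
        raise InsufficientSpikesError(f"{d.size} pairs < {MIN_SPIKES}")
    alternative = "greater" if which == "peak" else "less"
    if np.all(d == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(d, alternative=alternative)
    return PeakTestResult(
        peak_lag=float(observed.lags[i]),
        statistic=float(stat),
        p_value=float(p),
        n=int(d.size),
        which=which,
    )


def _extremum_lag(row: np.ndarray, lags: np.ndarray, mode: str) -> float | None:
    """Per-snippet extremum lag.  Peaks: global max, ties broken toward lag 0.
    Dips: the interior local minimum with the smallest value; equal-value
    plateaus resolve to their centre sample; ties broken toward lag 0."""
    if mode == "peak":
        m = row.max()
        cand = np.flatnonzero(row == m)
        return float(lags[cand[np.argmin(np.abs(lags[cand]))]])
    # dip: scan runs of equal values, interior runs lower than both neighbors
    n = row.size
    best_val, best_lag = np.inf, None
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and row[j + 1] == row[i]:
            j += 1
        left_ok = row[i - 1] > row[i]
        right_ok = j + 1 < n and row[j + 1] > row[i]
        if left_ok and right_ok:
            centre = (i + j) // 2 if abs(lags[(i + j) // 2]) <= abs(lags[-((i + j) // -2)]) \
                else -((i + j) // -2)
            val = row[i]
            lag = float(lags[centre])
            if val < best_val or (val == best_val and abs(lag) < abs(best_lag)):
                best_val, best_lag = val, lag
        i = j + 1
    return best_lag


def peak_dip_timing(
    per_spike: np.ndarray, lags: np.ndarray, mode: str = "peak"
) -> PeakDipTiming:
    """Per-spike timing of the largest peak (global max) or of the smallest
    interior local minimum of each snippet, with the median and a sign test
    of the timings against 0."""
    if mode not in ("peak", "dip"):
        raise ValidationError("mode must be 'peak' or 'dip'")
    times = []
    n_excluded = 0
    for row in np.asarray(per_spike, dtype=float):
        lag = _extremum_lag(row, lags, mode)
        if lag is None:
            n_excluded += 1
        else:
            times.append(lag)
    times = np.asarray(times)
    median = float(np.median(times)) if times.size else float("nan")
    p = sign_test(times) if times.size else float("nan")
    return PeakDipTiming(times=times, median=median, n_excluded=n_excluded,
                         sign_test_p=p, mode=mode)


def sign_test(x: np.ndarray, mu: float = 0.0) -> float:
    """Two-sided non-parametric sign test of the median of ``x`` against ``mu``.

    Exact binomial on the signs; zeros are discarded.
    """
    x = np.asarray(x, dtype=float)
    pos = int(np.count_nonzero(x > mu))
    neg = int(np.count_nonzero(x < mu))
    n = pos + neg
    if n == 0:
        return 1.0
    return float(stats.binomtest(pos, n, 0.5).pvalue)


def linear_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares R^2 of y ~ a + b x (fraction of variance explained)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
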