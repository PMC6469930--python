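"""Spatial firing-rate maps and Skaggs place information.

The tank is tiled with 16 cm square bins anchored at the corner of the
tank's bounding box.  A visit is counted when the head first enters a bin;
staying put does not accumulate visits.  Bins with fewer than five visits
over the whole trial are excluded.  Place information per spike,

    I = sum_i p_i (r_i / r_m) log2(r_i / r_m)   [bits/spike],

is tested against two permutation nulls: circular time-shifts of the whole
train (conserving relative spike timing; conservative) and uniform spike-time
shuffles (liberal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats

from .arena import ArenaLayout
from .errors import InsufficientSpikesError, UndefinedResultError, ValidationError
from .kinematics import TrackedTrajectory
from .triggered import SpikeTrain

__all__ = [
    "OccupancyGrid",
    "RateMap",
    "PlaceInfoResult",
    "build_occupancy",
    "build_rate_map",
    "place_information",
    "place_info_significance",
    "stationarity_check",
    "cross_trial_stationarity",
    "landmark_removal_effect",
    "landmark_removal_test",
]


@dataclass
class OccupancyGrid:
    """Binned time and visit occupancy of the arena."""

    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    time_s: np.ndarray  # (ny, nx) seconds
    visits: np.ndarray  # (ny, nx) int
    included: np.ndarray  # (ny, nx) bool, visits >= visit_min
    p: np.ndarray  # (ny, nx), sums to 1 over included bins
    dt: float
    frame_bins: np.ndarray  # flat bin index per video frame (internal reuse)

    @property
    def shape(self) -> tuple[int, int]:
        return self.time_s.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy


@dataclass
class RateMap:
    """Per-bin firing rate with the display copy clipped for plotting."""

    rate: np.ndarray  # (ny, nx) Hz, 0 where unoccupied
    r_m: float  # occupancy-weighted mean rate over included bins
    max_fr: float  # max firing rate per included bin (Hz)
    display: np.ndarray  # rate clipped at the display percentile
    clip_percentile: float
    n_spikes: int


@dataclass
class PlaceInfoResult:
    information: float  # bits/spike
    null_information: np.ndarray
    percentile_95: float
    significant: bool  # observed > 95th percentile of the null
    p_empirical: float  # fraction of surrogates >= observed
    p_ttest: float  # one-sample t-test of the null vs observed
    method: str
    n_spikes: int


def build_occupancy(
    traj: TrackedTrajectory,
    arena: ArenaLayout,
    bin_size: float = 16.0,
    visit_min: int = 5,
) -> OccupancyGrid:
    """Time and visit occupancy on a grid of ``bin_size`` cm squares.

    The grid origin sits at the corner of the tank's bounding box; the
    circular wall clips the outer bins.  Visits increment only when the
    head enters a bin it was not in on the previous frame.
    """
    if traj.n_frames == 0:
        raise ValidationError("empty trajectory")
    cx, cy = arena.tank_center
    x0, y0 = cx - arena.tank_radius, cy - arena.tank_radius
    n = int(math.ceil(2 * arena.tank_radius / bin_size))
    x_edges = x0 + bin_size * np.arange(n + 1)
    y_edges = y0 + bin_size * np.arange(n + 1)
    ix = np.clip(((traj.x - x0) // bin_size).astype(int), 0, n - 1)
    iy = np.clip(((traj.y - y0) // bin_size).astype(int), 0, n - 1)
    flat = iy * n + ix
    time_s = np.bincount(flat, minlength=n * n).reshape(n, n) * traj.dt
    entries = np.ones(flat.size, dtype=bool)
    entries[1:] = flat[1:] != flat[:-1]
    visits = np.bincount(flat[entries], minlength=n * n).reshape(n, n)
    included = visits >= visit_min
    p = np.where(included, time_s, 0.0)
    total = p.sum()
    if total > 0:
        p = p / total
    return OccupancyGrid(
        bin_size=bin_size, x_edges=x_edges, y_edges=y_edges, time_s=time_s,
        visits=visits, included=included, p=p, dt=traj.dt, frame_bins=flat,
    )


def _spike_bins(occ: OccupancyGrid, spikes: np.ndarray, traj: TrackedTrajectory) -> np.ndarray:
    """Flat bin index of each spike via the nearest video frame."""
    return occ.frame_bins[traj.frame_of(spikes)]


def _rate_from_counts(counts: np.ndarray, occ: OccupancyGrid) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ.time_s > 0, counts / occ.time_s, 0.0)
    return rate


def build_rate_map(
    occ: OccupancyGrid,
    spikes: SpikeTrain,
    traj: TrackedTrajectory,
    clip_percentile: float = 97.0,
) -> RateMap:
    """Per-bin firing rate: spike count divided by time spent in the bin.

    The display copy is clipped at the ``clip_percentile`` of the rate over
    included bins so rarely visited bins do not saturate the color scale.
    """
    n = occ.shape[0] * occ.shape[1]
    flat = _spike_bins(occ, spikes.spike_times, traj)
    counts = np.bincount(flat, minlength=n).reshape(occ.shape)
    rate = _rate_from_counts(counts, occ)
    r_m = float(np.sum(occ.p * rate))
    inc = rate[occ.included]
    if inc.size:
        clip = float(np.percentile(inc, clip_percentile))
        max_fr = float(inc.max())
    else:
        clip, max_fr = 0.0, 0.0
    return RateMap(
        rate=rate, r_m=r_m, max_fr=max_fr,
        display=np.minimum(rate, clip), clip_percentile=clip_percentile,
        n_spikes=len(spikes),
    )


def place_information(rate_map: RateMap, occ: OccupancyGrid) -> float:
    """Skaggs spatial information, bits per spike, over included bins.

    Zero-rate bins contribute 0 (the x log x -> 0 limit).  Undefined when
    the mean rate is zero.
    """
    return _information(rate_map.rate, occ.p, occ.included)


def _information(rate: np.ndarray, p: np.ndarray, included: np.ndarray) -> float:
    r = rate[included]
    w = p[included]
    r_m = float(np.sum(w * r))
    if r_m <= 0:
        raise UndefinedResultError("mean firing rate is zero; information undefined")
    q = r / r_m
    nz = q > 0
    return float(np.sum(w[nz] * q[nz] * np.log2(q[nz])))


def place_info_significance(
    spikes: SpikeTrain,
    traj: TrackedTrajectory,
    occ: OccupancyGrid,
    n_surrogates: int = 1000,
    method: str = "shift",
    min_shift: float = 30.0,
    rng: np.random.Generator | None = None,
    min_spikes: int = 10,
) -> PlaceInfoResult:
    """Permutation significance of place information.

    method='shift'   : circularly shift the whole train by a random time in
                       [min_shift, T - min_shift] (relative timing conserved;
                       conservative against within-trial rate drifts).
    method='shuffle' : redraw every spike time uniformly over the trial
                       (liberal).

    Significant iff the observed information exceeds the 95th percentile of
    the surrogate distribution; a one-sample t-test p of the surrogate
    distribution against the observed value is reported alongside.
    """
    if len(spikes) < min_spikes:
        raise InsufficientSpikesError(f"{len(spikes)} spikes < {min_spikes}")
    if method not in ("shift", "shuffle"):
        raise ValidationError("method must be 'shift' or 'shuffle'")
    rng = rng or np.random.default_rng()
    T = traj.duration
    nflat = occ.shape[0] * occ.shape[1]
    obs_counts = np.bincount(
        _spike_bins(occ, spikes.spike_times, traj), minlength=nflat
    ).reshape(occ.shape)
    observed = _information(_rate_from_counts(obs_counts, occ), occ.p, occ.included)
    null = np.empty(n_surrogates)
    for k in range(n_surrogates):
        if method == "shift":
            s = rng.uniform(min_shift, T - min_shift)
            t = np.mod(spikes.spike_times + s, T)
        else:
            t = rng.uniform(0.0, T, size=len(spikes))
        counts = np.bincount(_spike_bins(occ, t, traj), minlength=nflat).reshape(occ.shape)
        try:
            null[k] = _information(_rate_from_counts(counts, occ), occ.p, occ.included)
        except UndefinedResultError:
            null[k] = 0.0
    pct95 = float(np.percentile(null, 95))
    p_emp = float(np.mean(null >= observed))
    if np.ptp(null) == 0:
        p_t = 1.0 if null[0] >= observed else 0.0
    else:
        p_t = float(stats.ttest_1samp(null, observed, alternative="less").pvalue)
    return PlaceInfoResult(
        information=observed, null_information=null, percentile_95=pct95,
        significant=bool(observed > pct95), p_empirical=p_emp, p_ttest=p_t,
        method=method, n_spikes=len(spikes),
    )


@dataclass
class StationarityResult:
    rates_first: np.ndarray
    rates_second: np.ndarray
    statistic: float
    p_value: float


def _binned_rates(spike_times: np.ndarray, duration: float, n_bins: int) -> np.ndarray:
    edges = np.linspace(0.0, duration, n_bins + 1)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / (duration / n_bins)


def stationarity_check(
    spikes: SpikeTrain, trial_duration: float, n_bins: int = 10
) -> StationarityResult:
    """Within-trial stationarity: firing rate in 5 bins of each trial half,
    first half vs second half compared by Kruskal-Wallis."""
    if trial_duration <= 0 or n_bins < 2 or n_bins % 2:
        raise ValidationError("need a positive duration and an even bin count")
    rates = _binned_rates(spikes.spike_times, trial_duration, n_bins)
    half = n_bins // 2
    a, b = rates[:half], rates[half:]
    if np.ptp(rates) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(a, b)
    return StationarityResult(rates_first=a, rates_second=b,
                              statistic=float(stat), p_value=float(p))


def cross_trial_stationarity(
    spikes_a: SpikeTrain, duration_a: float,
    spikes_b: SpikeTrain, duration_b: float,
    n_bins: int = 10,
) -> StationarityResult:
    """Across-trial stationarity: all 10 binned rates of one trial vs the next."""
    ra = _binned_rates(spikes_a.spike_times, duration_a, n_bins)
    rb = _binned_rates(spikes_b.spike_times, duration_b, n_bins)
    if np.ptp(np.concatenate([ra, rb])) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(ra, rb)
    return StationarityResult(rates_first=ra, rates_second=rb,
                              statistic=float(stat), p_value=float(p))


@dataclass
class LandmarkEffect:
    mean_before: float
    mean_after: float
    norm_before: float  # divided by the larger of the two means
    norm_after: float
    ratio: float  # after / before
    n_bins_before: int
    n_bins_after: int


def _disc_bins(occ: OccupancyGrid, landmark, radius: float) -> np.ndarray:
    """Included bins whose centre lies within ``radius`` cm of the landmark
    polygon (distance to the polygon; 0 inside)."""
    cx, cy = occ.bin_centers()
    gx, gy = np.meshgrid(cx, cy)
    d = shapely.distance(shapely.points(gx.ravel(), gy.ravel()), landmark)
    return occ.included & (d.reshape(occ.shape) <= radius)


def landmark_removal_effect(
    map_before: RateMap,
    occ_before: OccupancyGrid,
    map_after: RateMap,
    occ_after: OccupancyGrid,
    landmark,
    radius: float = 10.0,
) -> LandmarkEffect:
    """Mean firing rate within ``radius`` cm of a landmark, before and after
    its removal, with rates normalised by the larger of the two."""
    sel_b = _disc_bins(occ_before, landmark, radius)
    sel_a = _disc_bins(occ_after, landmark, radius)
    if not sel_b.any() or not sel_a.any():
        raise UndefinedResultError("no included bins within the landmark disc")
    mb = float(map_before.rate[sel_b].mean())
    ma = float(map_after.rate[sel_a].mean())
    big = max(mb, ma)
    nb, na = (mb / big, ma / big) if big > 0 else (0.0, 0.0)
    ratio = ma / mb if mb > 0 else math.inf
    return LandmarkEffect(mean_before=mb, mean_after=ma, norm_before=nb,
                          norm_after=na, ratio=ratio,
                          n_bins_before=int(sel_b.sum()), n_bins_after=int(sel_a.sum()))


def landmark_removal_test(effects: list[LandmarkEffect]) -> tuple[float, float]:
    """Kruskal-Wallis on the pooled normalised rates (before vs after) across
    landmark-removal pairs.  Returns (H, p)."""
    before = [e.norm_before for e in effects]
    after = [e.norm_after for e in effects]
    if np.ptp(np.array(before + after)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(before, after)
    return float(h), float(p)
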