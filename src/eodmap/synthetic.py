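"""Synthetic trials with known ground truth.

Emulates a 30-60 min session of a pulse-type electric fish exploring a
1.5 m circular tank with landmarks, tracked at 15 Hz: a correlated random
walk with boundary reflection and landmark attraction (so occupancy is
biased toward walls and objects), backward-swim episodes (velocity
antiparallel to the body axis, as in B-scans), quiescent down-states, an
inhomogeneous gamma-renewal EOD train (quasi-regular; < 50 Hz during down
states, transients near objects), and sparse spike trains whose intensity
carries configurable place, swim-direction, EOD-rate, speed and
egocentric-landmark couplings — each one recoverable downstream.

Every effect the analyses are meant to detect is injected explicitly, so
each stage of the pipeline has a parameter-recovery test.  All randomness
flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely

from .arena import ArenaLayout
from .eod import EODPulseTrain, EODRateSeries
from .errors import ValidationError
from .kinematics import BACKWARD, FORWARD, QUIESCENT, TrackedTrajectory, compute_speed, wrap_angle
from .triggered import SpikeTrain

__all__ = [
    "MovementParams",
    "EODParams",
    "PlaceField",
    "Coupling",
    "LandmarkDriver",
    "GroundTruth",
    "TrajectoryTruth",
    "SyntheticSpikes",
    "generate_trajectory",
    "generate_eod_train",
    "homogeneous_eod_train",
    "generate_spikes",
    "generate_trial",
]


# ---------------------------------------------------------------------------
# parameter records

@dataclass
class MovementParams:
    """Correlated-random-walk movement model.

    Speeds in cm/s, durations in s, rates in events/s, angles in rad.
    """

    mean_speed: float = 8.0
    speed_sd: float = 3.0
    speed_tau: float = 2.0          # AR(1) relaxation time of speed
    max_speed: float = 25.0
    turn_sd: float = 1.0            # heading diffusion, rad / sqrt(s)
    max_turn: float = 0.6           # per-frame turn cap, rad
    backward_rate: float = 0.03     # backward-episode starts per second
    backward_dur_mean: float = 1.5
    quiescent_rate: float = 1.0 / 240.0
    quiescent_dur_mean: float = 30.0
    quiescent_dur_min: float = 5.0
    quiescent_speed: float = 0.3    # residual drift during quiescence
    goal_switch_mean: float = 12.0  # s between excursion-goal renewals
    landmark_goal_prob: float = 0.5  # fraction of goals placed beside an object
    goal_pull: float = 2.0          # steering toward the goal, rad/s
    goal_reached: float = 6.0       # cm: resample the goal when this close
    dwell_range: float = 6.0        # slow down within this distance of objects
    dwell_slow: float = 0.45
    wall_margin: float = 0.5
    tracking_noise: float = 0.03    # cm, video-tracking jitter added to positions


@dataclass
class EODParams:
    """Inhomogeneous gamma-renewal EOD train.

    Baseline when active, a lower rate during quiescent down-states, and a
    transient elevation decaying with distance from landmarks and the wall.
    ``isi_shape`` sets ISI regularity (1 = Poisson; real EOD trains are
    quasi-regular, hence the large default).
    """

    baseline_rate: float = 70.0
    down_rate: float = 40.0
    transient_amp: float = 30.0
    transient_scale: float = 4.0    # cm, exponential decay of the transient
    isi_shape: float = 25.0

    def validate(self) -> None:
        if self.baseline_rate <= 0 or self.down_rate <= 0:
            raise ValidationError("EOD rates must be positive")
        if self.isi_shape <= 0:
            raise ValidationError("isi_shape must be positive")


@dataclass
class PlaceField:
    """Gaussian multiplicative place field: gain peaks at ``peak_gain`` at the
    centre and decays with sigma = radius / 2."""

    center: tuple[float, float]
    radius: float = 15.0
    peak_gain: float = 10.0


@dataclass
class Coupling:
    """Covariate coupling: spike intensity at time t is modulated by the
    z-scored covariate at t + lag, so the spike-triggered average of the
    covariate peaks (gain > 0) or dips (gain < 0) at that lag."""

    lag: float
    gain: float


@dataclass
class LandmarkDriver:
    """Egocentric landmark drive: intensity is multiplied by ``gain`` in
    frames where the nearest landmark point lies within ``max_distance`` cm
    and in the given sector (relative to the anterior-third boundary of the
    body, ``body_length``/3 behind the head)."""

    gain: float = 6.0
    max_distance: float = 12.0
    sector: str = "posterior"  # or "anterior"
    body_length: float = 15.0


@dataclass
class GroundTruth:
    """All injected effects for one synthetic unit."""

    baseline_rate: float = 0.5       # Hz
    place_fields: list[PlaceField] = field(default_factory=list)
    direction_gain: float = 1.0      # intensity multiplier during backward swim
    forward_gain: float = 1.0        # intensity multiplier during forward swim
    eod_coupling: Coupling | None = None
    speed_coupling: Coupling | None = None
    landmark_driver: LandmarkDriver | None = None
    quiescent_factor: float = 0.0    # intensity multiplier during down-states
    down_state_schedule: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ValidationError("baseline_rate must be >= 0")
        if self.direction_gain < 0 or self.forward_gain < 0 or self.quiescent_factor < 0:
            raise ValidationError("gains must be >= 0")
        for f in self.place_fields:
            if f.peak_gain < 0 or f.radius <= 0:
                raise ValidationError("place-field radius > 0 and gain >= 0 required")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrajectoryTruth:
    """Generated trajectory plus its per-frame ground-truth labels."""

    trajectory: TrackedTrajectory
    labels: np.ndarray  # {forward, backward, quiescent} per frame
    seed: int | None = None

    def state_intervals(self, state: str) -> list[tuple[float, float]]:
        """Maximal [start, stop) intervals of a ground-truth state."""
        m = self.labels == state
        if not m.any():
            return []
        dt = self.trajectory.dt
        edges = np.diff(m.astype(int))
        starts = [0] if m[0] else []
        starts += list(np.flatnonzero(edges == 1) + 1)
        stops = list(np.flatnonzero(edges == -1) + 1)
        if m[-1]:
            stops.append(m.size)
        return [(float(i0 * dt), float(i1 * dt)) for i0, i1 in zip(starts, stops)]


@dataclass
class SyntheticSpikes:
    """A generated spike train with its ground truth and intensity embedded."""

    spikes: SpikeTrain
    truth: GroundTruth
    intensity: np.ndarray  # Hz per video frame


# ---------------------------------------------------------------------------
# precomputed arena fields for the movement loop

class _ArenaFields:
    """Gridded distance / blocking lookups (1 cm resolution)."""

    def __init__(self, arena: ArenaLayout, res: float = 1.0):
        self.res = res
        cx, cy = arena.tank_center
        r = arena.tank_radius
        self.x0, self.y0 = cx - r, cy - r
        n = int(math.ceil(2 * r / res)) + 1
        xs = self.x0 + res * np.arange(n)
        ys = self.y0 + res * np.arange(n)
        gx, gy = np.meshgrid(xs, ys)
        pts = shapely.points(gx.ravel(), gy.ravel())
        polys = list(arena.all_polygons().values())
        if polys:
            union = shapely.union_all(polys)
            dist = shapely.distance(pts, union).reshape(n, n)
        else:
            dist = np.full((n, n), np.inf)
        self.dist = dist
        blocked_polys = list(arena.blocked_polygons().values())
        if blocked_polys:
            bu = shapely.union_all(blocked_polys)
            # conservative: block everything within one grid cell of a polygon,
            # so any point whose nearest node is free is provably outside
            self.blocked = shapely.dwithin(pts, bu, res).reshape(n, n)
        else:
            self.blocked = np.zeros((n, n), dtype=bool)
        self.n = n
        self.boundaries = [p.exterior for p in polys]

    def _idx(self, x: float, y: float) -> tuple[int, int]:
        i = min(max(int(round((x - self.x0) / self.res)), 0), self.n - 1)
        j = min(max(int(round((y - self.y0) / self.res)), 0), self.n - 1)
        return j, i

    def landmark_distance(self, x: float, y: float) -> float:
        j, i = self._idx(x, y)
        return float(self.dist[j, i])

    def is_blocked(self, x: float, y: float) -> bool:
        j, i = self._idx(x, y)
        return bool(self.blocked[j, i])


# ---------------------------------------------------------------------------
# trajectory

def generate_trajectory(
    arena: ArenaLayout,
    duration: float,
    frame_rate: float = 15.0,
    params: MovementParams | None = None,
    seed: int | np.random.Generator = 0,
) -> TrajectoryTruth:
    """Simulate a tracked swim: correlated random walk on heading steered by
    excursion goals (a fraction of which sit beside landmarks), with boundary
    avoidance, dwell slow-down near objects, and interleaved backward-swim
    and quiescent episodes.

    Returns the trajectory together with per-frame ground-truth labels.
    """
    if duration <= 0 or frame_rate <= 0:
        raise ValidationError("duration and frame_rate must be positive")
    params = params or MovementParams()
    dt = 1.0 / frame_rate
    if params.max_speed * dt > arena.tank_radius:
        raise ValidationError("max_speed would cross the tank in a single frame")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fields = _ArenaFields(arena)
    n = int(round(duration * frame_rate))
    cx, cy = arena.tank_center
    R = arena.tank_radius

    # start anywhere valid
    while True:
        x = cx + rng.uniform(-0.7, 0.7) * R
        y = cy + rng.uniform(-0.7, 0.7) * R
        if math.hypot(x - cx, y - cy) < R - 2 and not fields.is_blocked(x, y):
            break
    h = rng.uniform(-math.pi, math.pi)
    speed = params.mean_speed

    def sample_goal() -> tuple[float, float]:
        for _ in range(20):
            if fields.boundaries and rng.random() < params.landmark_goal_prob:
                ring = fields.boundaries[rng.integers(len(fields.boundaries))]
                q = ring.interpolate(rng.uniform(0.0, ring.length))
                ang = rng.uniform(-math.pi, math.pi)
                off = rng.uniform(1.5, 4.0)
                gx_, gy_ = q.x + off * math.cos(ang), q.y + off * math.sin(ang)
            else:
                rr = R * math.sqrt(rng.random())
                aa = rng.uniform(-math.pi, math.pi)
                gx_, gy_ = cx + rr * math.cos(aa), cy + rr * math.sin(aa)
            if math.hypot(gx_ - cx, gy_ - cy) < R - 2 and not fields.is_blocked(gx_, gy_):
                return gx_, gy_
        return cx, cy

    goal = sample_goal()
    goal_left = rng.exponential(params.goal_switch_mean)

    turn_noise = rng.standard_normal(n) * params.turn_sd * math.sqrt(dt)
    speed_noise = rng.standard_normal(n) * params.speed_sd * math.sqrt(2 * dt / params.speed_tau)
    u_state = rng.random(n)
    u_quiet = rng.random(n)
    escape_noise = rng.standard_normal(n) * 0.4

    xs = np.empty(n)
    ys = np.empty(n)
    hs = np.empty(n)
    labels = np.empty(n, dtype="U9")

    state = FORWARD
    state_left = 0.0
    p_b = params.backward_rate * dt
    p_q = params.quiescent_rate * dt
    inner = R - params.wall_margin
    for i in range(n):
        # episode bookkeeping
        if state != FORWARD:
            state_left -= dt
            if state_left <= 0:
                state = FORWARD
        else:
            if u_state[i] < p_b:
                state = BACKWARD
                state_left = rng.exponential(params.backward_dur_mean)
            elif u_state[i] < p_b + p_q:
                state = QUIESCENT
                state_left = max(rng.exponential(params.quiescent_dur_mean),
                                 params.quiescent_dur_min)
        xs[i], ys[i], hs[i] = x, y, h
        labels[i] = state

        d_lm = fields.landmark_distance(x, y)
        if state == QUIESCENT:
            s_eff = u_quiet[i] * params.quiescent_speed
            h = h + 0.05 * turn_noise[i]
        else:
            # dwell slow-down acts on the AR target so speed decelerates
            # smoothly when the fish closes in on an object
            target = params.mean_speed * (
                params.dwell_slow if d_lm < params.dwell_range else 1.0)
            speed += (target - speed) * dt / params.speed_tau + speed_noise[i]
            speed = min(max(speed, 0.5), params.max_speed)
            s_eff = speed
            dh = max(-params.max_turn, min(params.max_turn, turn_noise[i]))
            goal_left -= dt
            if goal_left <= 0 or math.hypot(goal[0] - x, goal[1] - y) < params.goal_reached:
                goal = sample_goal()
                goal_left = rng.exponential(params.goal_switch_mean)
            if state == FORWARD:
                want = math.atan2(goal[1] - y, goal[0] - x)
                pull = params.goal_pull * dt * math.remainder(want - h, math.tau)
                dh += max(-0.7 * params.max_turn, min(0.7 * params.max_turn, pull))
            h = h + dh
        h = math.remainder(h, math.tau)

        sign = -1.0 if state == BACKWARD else 1.0
        step = sign * s_eff * dt
        nx_, ny_ = x + step * math.cos(h), y + step * math.sin(h)
        if math.hypot(nx_ - cx, ny_ - cy) > inner or fields.is_blocked(nx_, ny_):
            # steer toward the tank centre (movement direction, not body axis)
            aim = math.atan2(cy - y, cx - x)
            h = math.remainder(aim + (math.pi if state == BACKWARD else 0.0)
                               + escape_noise[i], math.tau)
            nx_, ny_ = x + step * math.cos(h), y + step * math.sin(h)
            if math.hypot(nx_ - cx, ny_ - cy) > inner or fields.is_blocked(nx_, ny_):
                nx_, ny_ = x, y  # stay put this frame
        x, y = nx_, ny_

    if params.tracking_noise > 0:
        # video-tracking jitter; kept small enough not to disturb labels
        xs = xs + rng.standard_normal(n) * params.tracking_noise
        ys = ys + rng.standard_normal(n) * params.tracking_noise
    traj = TrackedTrajectory(times=np.arange(n) * dt, x=xs, y=ys, heading=wrap_angle(hs))
    return TrajectoryTruth(
        trajectory=traj, labels=labels,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


# ---------------------------------------------------------------------------
# EOD train

def _renewal_from_rate(
    times: np.ndarray, rate: np.ndarray, shape: float,
    duration: float, rng: np.random.Generator,
) -> EODPulseTrain:
    """Inhomogeneous gamma-renewal train by time rescaling: unit-mean
    gamma(shape) increments in integrated-rate time, warped back."""
    if np.any(rate <= 0):
        raise ValidationError("EOD rate must be positive everywhere")
    dt = times[1] - times[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    grid = np.concatenate([times, [times[-1] + dt]])
    total = cum[-1]
    draws: list[np.ndarray] = []
    mass = 0.0
    expect = int(total) + 1
    while mass < total:
        block = rng.gamma(shape, 1.0 / shape, size=expect + 100)
        draws.append(block)
        mass += block.sum()
    s = np.cumsum(np.concatenate(draws))
    s = s[s < total]
    pulses = np.interp(s, cum, grid)
    pulses = pulses[pulses < duration]
    return EODPulseTrain(pulse_times=pulses, trial_duration=duration)


def homogeneous_eod_train(
    rate: float, duration: float, shape: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EODPulseTrain:
    """Constant-rate gamma-renewal train (shape = 1 is Poisson)."""
    if rate <= 0:
        raise ValidationError("rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(math.ceil(duration / 0.1)) + 1) * 0.1
    return _renewal_from_rate(t, np.full(t.size, float(rate)), shape, duration, rng)


def generate_eod_train(
    traj_truth: TrajectoryTruth,
    arena: ArenaLayout,
    params: EODParams | None = None,
    seed: int | np.random.Generator = 0,
) -> EODPulseTrain:
    """EOD pulse train driven by the behavioral state and proximity to objects.

    Rate = down_rate during quiescent frames, else baseline plus a transient
    that decays exponentially with distance to the nearest landmark or the
    tank wall.
    """
    params = params or EODParams()
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = traj_truth.trajectory
    d_lm = arena.distance_to_landmarks(traj.x, traj.y)
    d = np.minimum(d_lm, np.maximum(arena.distance_to_wall(traj.x, traj.y), 0.0))
    rate = params.baseline_rate + params.transient_amp * np.exp(-d / params.transient_scale)
    rate = np.where(traj_truth.labels == QUIESCENT, params.down_rate, rate)
    return _renewal_from_rate(traj.times, rate, params.isi_shape, traj.duration, rng)


# ---------------------------------------------------------------------------
# spikes

def _ego_nearest_landmark(
    traj: TrackedTrajectory, arena: ArenaLayout
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame egocentric coordinates (right, forward) and distance of the
    nearest landmark point."""
    polys = list(arena.all_polygons().values())
    if not polys:
        n = traj.n_frames
        inf = np.full(n, np.inf)
        return inf, inf, inf
    union = shapely.union_all(polys)
    pts = shapely.points(traj.x, traj.y)
    seg = shapely.shortest_line(pts, union)
    coords = shapely.get_coordinates(seg).reshape(-1, 2, 2)
    near = coords[:, 1, :]
    dx = near[:, 0] - traj.x
    dy = near[:, 1] - traj.y
    fx, fy = np.cos(traj.heading), np.sin(traj.heading)
    forward = dx * fx + dy * fy
    right = dx * fy - dy * fx
    return right, forward, np.hypot(dx, dy)


def generate_spikes(
    traj_truth: TrajectoryTruth,
    eod_rate: EODRateSeries,
    truth: GroundTruth,
    arena: ArenaLayout | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticSpikes:
    """Sample a sparse spike train from an inhomogeneous Poisson intensity.

    intensity = baseline x place gain x direction gain x EOD-coupling gain
    x speed-coupling gain x egocentric-landmark gain, multiplied by
    ``quiescent_factor`` during ground-truth quiescence.  Covariate coupling
    gains are exp(gain x z-scored covariate at t + lag), normalised to unit
    mean so the baseline keeps its meaning.
    """
    truth.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = traj_truth.trajectory
    lam = np.full(traj.n_frames, truth.baseline_rate, dtype=float)

    gain = np.ones(traj.n_frames)
    for fld in truth.place_fields:
        d2 = (traj.x - fld.center[0]) ** 2 + (traj.y - fld.center[1]) ** 2
        sigma = fld.radius / 2.0
        gain += (fld.peak_gain - 1.0) * np.exp(-d2 / (2 * sigma**2))
    lam *= gain
    lam *= np.where(traj_truth.labels == BACKWARD, truth.direction_gain, 1.0)
    lam *= np.where(traj_truth.labels == FORWARD, truth.forward_gain, 1.0)

    def coupling_gain(values: np.ndarray, c: Coupling) -> np.ndarray:
        shifted = np.interp(traj.times + c.lag, traj.times, values)
        sd = shifted.std()
        z = (shifted - shifted.mean()) / sd if sd > 0 else np.zeros_like(shifted)
        g = np.exp(c.gain * np.clip(z, -2.5, 2.5))  # saturating modulation
        return g / g.mean()

    if truth.eod_coupling is not None:
        r = np.interp(traj.times, eod_rate.times, eod_rate.rate)
        lam *= coupling_gain(r, truth.eod_coupling)
    if truth.speed_coupling is not None:
        lam *= coupling_gain(compute_speed(traj), truth.speed_coupling)
    if truth.landmark_driver is not None:
        if arena is None:
            raise ValidationError("landmark_driver requires the arena layout")
        drv = truth.landmark_driver
        right, forward, dist = _ego_nearest_landmark(traj, arena)
        boundary = -drv.body_length / 3.0
        in_sector = forward < boundary if drv.sector == "posterior" else forward > boundary
        lam *= np.where((dist <= drv.max_distance) & in_sector, drv.gain, 1.0)
    lam[traj_truth.labels == QUIESCENT] *= truth.quiescent_factor

    dt = traj.dt
    counts = rng.poisson(lam * dt)
    jitter = rng.uniform(-0.5, 0.5, size=int(counts.sum()))
    times = np.repeat(traj.times, counts) + jitter * dt
    times = np.sort(np.clip(times, 0.0, traj.duration - 1e-9))
    times = times[np.concatenate([[True], np.diff(times) > 0])]
    truth.down_state_schedule = traj_truth.state_intervals(QUIESCENT)
    spikes = SpikeTrain(spike_times=times, trial_duration=traj.duration)
    return SyntheticSpikes(spikes=spikes, truth=truth, intensity=lam)


def generate_trial(
    arena: ArenaLayout,
    truths: dict[str, GroundTruth],
    duration: float = 1800.0,
    frame_rate: float = 15.0,
    movement: MovementParams | None = None,
    eod_params: EODParams | None = None,
    seed: int = 0,
    trial_id: str = "synthetic",
):
    """Generate a complete trial bundle (arena + trajectory + EOD + units).

    The master seed deterministically spawns independent streams for the
    trajectory, the EOD train and each unit.  The returned bundle carries a
    ground-truth sidecar (labels, down-state schedule, per-unit truths).
    """
    from .eod import instantaneous_eod_rate
    from .io import TrialBundle

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 + len(truths))
    tt = generate_trajectory(
        arena, duration, frame_rate, movement,
        seed=np.random.default_rng(streams[0]),
    )
    eod = generate_eod_train(tt, arena, eod_params, seed=np.random.default_rng(streams[1]))
    rate = instantaneous_eod_rate(eod, grid=tt.trajectory.times)
    units: dict[str, SpikeTrain] = {}
    unit_truths: dict[str, dict] = {}
    for (name, truth), stream in zip(sorted(truths.items()), streams[2:]):
        truth.seed = seed
        syn = generate_spikes(tt, rate, truth, arena=arena,
                              seed=np.random.default_rng(stream))
        syn.spikes.unit_id = name
        syn.spikes.trial_id = trial_id
        units[name] = syn.spikes
        unit_truths[name] = truth.to_dict()
    sidecar = {
        "seed": seed,
        "labels": tt.labels.tolist(),
        "down_state_schedule": tt.state_intervals(QUIESCENT),
        "units": unit_truths,
    }
    return TrialBundle(trial_id=trial_id, arena=arena, trajectory=tt.trajectory,
                       eod=eod, units=units, ground_truth=sidecar), tt
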