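"""Egocentric landmark analysis: STLM/PTLM maps and preference indices.

A binary raster marks where landmarks and the tank wall sit in the video
frame (one element per 10 x 10 pixel block).  At each spike the raster is
rotated and translated so the fish sits at the centre with its head facing
north, and summed over spikes (STLM).  The same accumulation over regularly
down-sampled positions (every 1.33 s) gives the occupancy-matched PTLM.
Their quotient, masked where the fish's surroundings rarely contained a
landmark and cropped to a 10 cm window, estimates the probability that a
landmark occupied each egocentric location at spike time.

The swim-direction preference index of a unit lives here too:
(FR_forward - FR_backward) / (FR_forward + FR_backward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .arena import ArenaLayout
from .errors import InsufficientSpikesError, UndefinedResultError, ValidationError
from .kinematics import BACKWARD, FORWARD, SwimSegmentLabels, TrackedTrajectory
from .triggered import SpikeTrain

__all__ = [
    "LandmarkRaster",
    "EgocentricMap",
    "PreferenceVector",
    "rasterize_arena",
    "egocentric_transform",
    "accumulate_stlm_ptlm",
    "ap_lr_preference",
    "direction_preference_index",
]


@dataclass
class LandmarkRaster:
    """Binary raster of landmark / tank-boundary presence in the video frame.

    ``matrix`` has shape (ny, nx) with row 0 at the *bottom* (y increases
    with row index, matching the cm frame).  Element (j, i) covers the
    square [x0 + i*el, x0 + (i+1)*el) x [y0 + j*el, y0 + (j+1)*el).
    """

    matrix: np.ndarray  # (ny, nx) of {0, 1}
    x0: float  # cm, lower-left corner of element (0, 0)
    y0: float
    element_cm: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValidationError("raster matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("raster matrix must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.shape[1]) + 0.5) * self.element_cm

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.shape[0]) + 0.5) * self.element_cm


def rasterize_arena(arena: ArenaLayout, block_px: int = 10) -> LandmarkRaster:
    """Rasterise landmarks and the tank wall onto the video element grid.

    One element per ``block_px`` x ``block_px`` video pixels (160 x 120
    elements for a 1600 x 1200 frame); an element is 1 when its footprint
    intersects any landmark polygon (home included) or the tank boundary
    circle, else 0.
    """
    w_px, h_px = arena.video_size
    nx, ny = w_px // block_px, h_px // block_px
    el = block_px * arena.pixel_scale
    cx, cy = arena.tank_center
    x0 = cx - nx * el / 2.0
    y0 = cy - ny * el / 2.0
    xs = x0 + np.arange(nx) * el
    ys = y0 + np.arange(ny) * el
    gx, gy = np.meshgrid(xs, ys)
    boxes = shapely.box(gx.ravel(), gy.ravel(), gx.ravel() + el, gy.ravel() + el)
    hit = np.zeros(boxes.size, dtype=bool)
    wall = shapely.Point(arena.tank_center).buffer(arena.tank_radius, quad_segs=90).exterior
    hit |= shapely.intersects(boxes, wall)
    for poly in arena.all_polygons().values():
        hit |= shapely.intersects(boxes, poly)
    return LandmarkRaster(
        matrix=hit.reshape(ny, nx).astype(np.uint8), x0=x0, y0=y0, element_cm=el
    )


def _ego_offsets(raster: LandmarkRaster) -> tuple[np.ndarray, np.ndarray, int, int]:
    ny, nx = raster.shape
    ci, cj = nx // 2, ny // 2
    ex = (np.arange(nx) - ci) * raster.element_cm  # + = fish's right
    ey = (np.arange(ny) - cj) * raster.element_cm  # + = ahead of the fish
    return ex, ey, ci, cj


def egocentric_transform(
    raster: LandmarkRaster, position: tuple[float, float], heading: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate + translate the raster so the fish sits at the centre element
    with its head facing north (up).

    Returns ``(ego, valid)``: the nearest-neighbour-resampled binary matrix
    and a mask of elements whose source location fell inside the raster
    extent (out-of-frame elements are 0 and invalid).

    In the output, +columns = the fish's right, +rows = ahead of the fish.
    """
    ex, ey, _, _ = _ego_offsets(raster)
    fx, fy = float(np.cos(heading)), float(np.sin(heading))
    rx, ry = fy, -fx  # unit vector to the fish's right
    exg, eyg = np.meshgrid(ex, ey)  # (ny, nx) grids of ego offsets
    wx = position[0] + exg * rx + eyg * fx
    wy = position[1] + exg * ry + eyg * fy
    ii = np.floor((wx - raster.x0) / raster.element_cm).astype(int)
    jj = np.floor((wy - raster.y0) / raster.element_cm).astype(int)
    ny, nx = raster.shape
    valid = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
    out = np.zeros(raster.shape, dtype=np.float64)
    out[valid] = raster.matrix[jj[valid], ii[valid]]
    return out, valid


@dataclass
class EgocentricMap:
    """Accumulated STLM/PTLM and the derived landmark-presence probability."""

    stlm: np.ndarray  # full-raster spike-triggered sum
    ptlm: np.ndarray  # full-raster position-triggered sum
    probability: np.ndarray  # cropped to the window, normalised to its max
    excluded: np.ndarray  # cropped mask: True where PTLM too low / invalid
    ego_x: np.ndarray  # cm offsets of the cropped columns (+ = right)
    ego_y: np.ndarray  # cm offsets of the cropped rows (+ = anterior)
    n_spikes: int
    n_position_samples: int
    element_cm: float


def accumulate_stlm_ptlm(
    raster: LandmarkRaster,
    traj: TrackedTrajectory,
    spikes: SpikeTrain,
    downsample: int = 20,
    window_cm: float = 10.0,
    exclusion_percentile: float = 10.0,
    min_spikes: int = 10,
) -> EgocentricMap:
    """Spike- and position-triggered landmark matrices and their quotient.

    STLM sums the egocentric raster at the pose of the video frame nearest
    each spike; PTLM sums it at every ``downsample``-th frame (20 frames =
    1.33 s at 15 Hz).  The quotient is masked where PTLM is below its lower
    ``exclusion_percentile`` (locations rarely occupied by any landmark),
    cropped to +/-``window_cm`` around the fish, and normalised to its max.
    """
    if len(spikes) < min_spikes:
        raise InsufficientSpikesError(f"{len(spikes)} spikes < {min_spikes}")
    stlm = np.zeros(raster.shape)
    for f in traj.frame_of(spikes.spike_times):
        ego, _ = egocentric_transform(raster, (traj.x[f], traj.y[f]), traj.heading[f])
        stlm += ego
    ptlm = np.zeros(raster.shape)
    frames = np.arange(0, traj.n_frames, downsample)
    for f in frames:
        ego, _ = egocentric_transform(raster, (traj.x[f], traj.y[f]), traj.heading[f])
        ptlm += ego
    cutoff = np.percentile(ptlm, exclusion_percentile)
    excluded_full = (ptlm <= cutoff) | (ptlm == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob_full = np.where(excluded_full, np.nan, stlm / np.where(ptlm > 0, ptlm, 1.0))
    ex, ey, _, _ = _ego_offsets(raster)
    keep_x = np.abs(ex) <= window_cm + 1e-9
    keep_y = np.abs(ey) <= window_cm + 1e-9
    prob = prob_full[np.ix_(keep_y, keep_x)]
    excl = excluded_full[np.ix_(keep_y, keep_x)]
    finite = prob[~excl]
    peak = np.nanmax(finite) if finite.size else np.nan
    if np.isfinite(peak) and peak > 0:
        prob = prob / peak
    return EgocentricMap(
        stlm=stlm, ptlm=ptlm, probability=prob, excluded=excl,
        ego_x=ex[keep_x], ego_y=ey[keep_y],
        n_spikes=len(spikes), n_position_samples=frames.size,
        element_cm=raster.element_cm,
    )


@dataclass
class PreferenceVector:
    """Left-right and anterior-posterior landmark preference of a unit.

    Positive lr_index = landmark probability peaks to the fish's right;
    positive ap_index = anterior of the anterior-third boundary.
    """

    lr_index: float
    ap_index: float
    magnitude: float
    angle: float  # atan2(ap, lr), radians


def ap_lr_preference(emap: EgocentricMap, body_length: float = 15.0) -> PreferenceVector:
    """Region-maxima preference indices from an egocentric probability map.

    The window splits into left/right of the body midline and, along the
    body axis, anterior/posterior of the boundary between the anterior 1/3
    and posterior 2/3 of the body (``body_length``/3 behind the head, which
    sits at the origin).  Each index is (max_pos - max_neg)/(max_pos + max_neg)
    over region maxima of the probability map.
    """
    prob = np.where(emap.excluded, np.nan, emap.probability)
    gx, gy = np.meshgrid(emap.ego_x, emap.ego_y)
    ap_zero = -body_length / 3.0
    regions = {
        "right": gx > 0,
        "left": gx < 0,
        "anterior": gy > ap_zero,
        "posterior": gy < ap_zero,
    }
    maxima = {}
    for name, sel in regions.items():
        vals = prob[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise UndefinedResultError(f"egocentric region {name!r} entirely masked")
        maxima[name] = float(vals.max())
    lr_den = maxima["right"] + maxima["left"]
    ap_den = maxima["anterior"] + maxima["posterior"]
    if lr_den == 0 or ap_den == 0:
        raise UndefinedResultError("all region maxima are zero")
    lr = (maxima["right"] - maxima["left"]) / lr_den
    ap = (maxima["anterior"] - maxima["posterior"]) / ap_den
    return PreferenceVector(
        lr_index=lr, ap_index=ap,
        magnitude=float(np.hypot(lr, ap)), angle=float(np.arctan2(ap, lr)),
    )


def direction_preference_index(
    spikes: SpikeTrain,
    labels: SwimSegmentLabels,
    traj: TrackedTrajectory,
) -> float:
    """(FR_forward - FR_backward) / (FR_forward + FR_backward).

    FR in each state = spikes in frames of that state / total time in the
    state (turns are already pooled into the states by the classifier).
    Negative values mean preference for spiking during backward swims.
    """
    dt = traj.dt
    t_fwd = labels.time_in_state(FORWARD, dt)
    t_bwd = labels.time_in_state(BACKWARD, dt)
    if t_fwd == 0 or t_bwd == 0:
        raise UndefinedResultError("zero time in forward or backward state")
    spike_labels = labels.labels[traj.frame_of(spikes.spike_times)]
    fr_fwd = np.count_nonzero(spike_labels == FORWARD) / t_fwd
    fr_bwd = np.count_nonzero(spike_labels == BACKWARD) / t_bwd
    if fr_fwd + fr_bwd == 0:
        raise UndefinedResultError("unit fired no spikes while swimming")
    return float((fr_fwd - fr_bwd) / (fr_fwd + fr_bwd))
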