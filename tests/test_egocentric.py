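"""Direction preference and egocentric landmark (STLM/PTLM) analysis."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from eodmap.arena import ArenaLayout, default_arena
from eodmap.egocentric import (
    EgocentricMap,
    LandmarkRaster,
    accumulate_stlm_ptlm,
    ap_lr_preference,
    direction_preference_index,
    egocentric_transform,
    rasterize_arena,
)
from eodmap.errors import UndefinedResultError
from eodmap.kinematics import SwimSegmentLabels, TrackedTrajectory
from eodmap.triggered import SpikeTrain

FPS = 15.0


def labelled_trajectory(labels):
    n = len(labels)
    t = np.arange(n) / FPS
    traj = TrackedTrajectory(times=t, x=np.zeros(n), y=np.zeros(n), heading=np.zeros(n))
    return traj, SwimSegmentLabels(labels=np.asarray(labels, dtype="U9"),
                                   speed=np.full(n, 5.0))


def spikes_in_frames(frames):
    return SpikeTrain(spike_times=np.sort(np.asarray(frames) / FPS))


class TestDirectionPreference:
    def test_all_forward_spikes_give_plus_one(self):
        traj, labels = labelled_trajectory(["forward"] * 60 + ["backward"] * 60)
        dpi = direction_preference_index(spikes_in_frames([3, 10, 20, 30]), labels, traj)
        assert dpi == 1.0

    def test_one_vs_three_hertz_gives_minus_half(self):
        # 10 s forward with 10 spikes (1 Hz), 10 s backward with 30 spikes (3 Hz)
        traj, labels = labelled_trajectory(["forward"] * 150 + ["backward"] * 150)
        fwd = np.arange(10) * 15
        bwd = 150 + np.arange(30) * 5
        dpi = direction_preference_index(
            spikes_in_frames(np.concatenate([fwd, bwd])), labels, traj)
        assert dpi == pytest.approx(-0.5)

    def test_zero_time_in_state_undefined(self):
        traj, labels = labelled_trajectory(["forward"] * 100)
        with pytest.raises(UndefinedResultError):
            direction_preference_index(spikes_in_frames([5, 10]), labels, traj)


class TestEgocentricTransform:
    def test_north_heading_at_centre_is_identity(self, ego_raster):
        r = ego_raster
        cx = r.x0 + (r.shape[1] // 2 + 0.5) * r.element_cm
        cy = r.y0 + (r.shape[0] // 2 + 0.5) * r.element_cm
        ego, valid = egocentric_transform(r, (cx, cy), math.pi / 2)
        assert valid.all()
        assert np.array_equal(ego, r.matrix.astype(float))

    def test_landmark_ahead_maps_to_north(self):
        # single landmark element 5 cm east of the fish; heading east ->
        # the landmark should appear 5 cm north of the centre
        m = np.zeros((41, 41), dtype=np.uint8)
        el = 1.0
        x0 = y0 = -20.5
        m[20, 25] = 1  # world position (5, 0)
        r = LandmarkRaster(matrix=m, x0=x0, y0=y0, element_cm=el)
        ego, _ = egocentric_transform(r, (0.0, 0.0), 0.0)
        hits = np.argwhere(ego == 1)
        assert len(hits) == 1
        j, i = hits[0]
        assert (i - 20, j - 20) == (0, 5)  # (right, forward) = (0, +5)

    def test_matches_bruteforce_inverse_mapping(self, ego_raster, rng):
        r = ego_raster
        pos = (rng.uniform(-40, 40), rng.uniform(-30, 30))
        h = rng.uniform(-math.pi, math.pi)
        ego, valid = egocentric_transform(r, pos, h)
        ny, nx = r.shape
        ci, cj = nx // 2, ny // 2
        fx, fy = math.cos(h), math.sin(h)
        for j in range(0, ny, 7):  # subsample the grid for speed
            for i in range(0, nx, 7):
                ex = (i - ci) * r.element_cm
                ey = (j - cj) * r.element_cm
                wx = pos[0] + ex * fy + ey * fx
                wy = pos[1] - ex * fx + ey * fy
                ii = math.floor((wx - r.x0) / r.element_cm)
                jj = math.floor((wy - r.y0) / r.element_cm)
                if 0 <= ii < nx and 0 <= jj < ny:
                    assert valid[j, i]
                    assert ego[j, i] == r.matrix[jj, ii]
                else:
                    assert not valid[j, i]

    def test_inverse_pose_round_trip(self, ego_raster):
        r = ego_raster
        cx = r.x0 + (r.shape[1] // 2 + 0.5) * r.element_cm
        cy = r.y0 + (r.shape[0] // 2 + 0.5) * r.element_cm
        h = 0.7
        e1, v1 = egocentric_transform(r, (cx, cy), h)
        r2 = LandmarkRaster(matrix=(e1 > 0).astype(np.uint8), x0=r.x0, y0=r.y0,
                            element_cm=r.element_cm)
        e2, v2 = egocentric_transform(r2, (cx, cy), math.pi - h)
        both = v1 & v2
        agreement = np.mean(e2[both] == r.matrix[both])
        assert agreement > 0.98  # nearest-neighbour edge quantisation only


@pytest.fixture(scope="module")
def ego_raster():
    return rasterize_arena(default_arena())


class TestRasterisation:
    def test_shape_and_binary(self, ego_raster):
        assert ego_raster.shape == (120, 160)
        assert set(np.unique(ego_raster.matrix)) <= {0, 1}

    def test_wall_and_landmarks_marked(self, ego_raster):
        arena = default_arena()
        # element containing a wall point
        wx, wy = arena.tank_radius, 0.0
        i = int((wx - ego_raster.x0) // ego_raster.element_cm)
        j = int((wy - ego_raster.y0) // ego_raster.element_cm)
        assert ego_raster.matrix[j, i] == 1
        # element far inside open water
        i0 = int((0 - ego_raster.x0) // ego_raster.element_cm)
        j0 = int((-20 - ego_raster.y0) // ego_raster.element_cm)
        assert ego_raster.matrix[j0, i0] == 0


class TestAccumulation:
    def test_fixed_offset_landmark_peaks_at_that_offset(self):
        # one small landmark; every spike has it exactly 5 cm ahead
        arena = ArenaLayout(
            tank_radius=75.0,
            landmarks={"dot": Polygon([(-1, 19), (1, 19), (1, 21), (-1, 21)])},
            pixel_scale=0.125,
        )
        raster = rasterize_arena(arena)
        n = 1200
        t = np.arange(n) / FPS
        angles = np.linspace(-math.pi, math.pi, n)
        # fish circles the landmark centre at 8 cm, always facing it, so the
        # landmark's near edge sits ~7 cm dead ahead at every spike
        x = 0 + 8 * np.cos(angles)
        y = 20 + 8 * np.sin(angles)
        heading = np.arctan2(20 - y, 0 - x)
        traj = TrackedTrajectory(times=t, x=x, y=y, heading=heading)
        spikes = SpikeTrain(spike_times=t[5:-5:12].copy())
        emap = accumulate_stlm_ptlm(raster, traj, spikes, downsample=20)
        valid = np.where(emap.excluded, -1.0, emap.probability)
        j, i = np.unravel_index(np.argmax(valid), valid.shape)
        assert 5.0 <= emap.ego_y[j] <= 10.0  # anterior, around the near edge
        assert abs(emap.ego_x[i]) <= 2.5  # on the midline

    def test_uniform_spike_subsample_gives_flat_quotient(self, ego_raster, rng):
        arena = default_arena()
        from eodmap import synthetic as syn

        tt = syn.generate_trajectory(arena, 600.0, seed=202)
        traj = tt.trajectory
        frames = rng.choice(np.arange(0, traj.n_frames, 20), size=360, replace=False)
        spikes = SpikeTrain(spike_times=np.sort(traj.times[np.sort(frames)]))
        emap = accumulate_stlm_ptlm(ego_raster, traj, spikes, downsample=20)
        vals = emap.probability[~emap.excluded]
        # the quotient is flat up to subsampling noise
        assert np.nanstd(vals) / np.nanmean(vals) < 0.5

    def test_probability_bounded_and_masked(self, ego_raster):
        arena = default_arena()
        from eodmap import synthetic as syn

        tt = syn.generate_trajectory(arena, 300.0, seed=203)
        traj = tt.trajectory
        spikes = SpikeTrain(spike_times=traj.times[10:-10:40].copy())
        emap = accumulate_stlm_ptlm(ego_raster, traj, spikes)
        vals = emap.probability[~emap.excluded]
        assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))
        # masked elements never contribute a probability
        assert np.all(np.isnan(emap.probability[emap.excluded]))


def ego_map_from(prob, element_cm=1.25):
    ny, nx = prob.shape
    ex = (np.arange(nx) - nx // 2) * element_cm
    ey = (np.arange(ny) - ny // 2) * element_cm
    return EgocentricMap(
        stlm=prob, ptlm=np.ones_like(prob), probability=prob,
        excluded=np.zeros_like(prob, dtype=bool), ego_x=ex, ego_y=ey,
        n_spikes=100, n_position_samples=1000, element_cm=element_cm,
    )


class TestPreferenceVector:
    def test_anterior_right_mass_gives_plus_plus(self):
        prob = np.zeros((17, 17))
        prob[14, 12] = 1.0  # ahead and to the right
        vec = ap_lr_preference(ego_map_from(prob), body_length=15.0)
        assert vec.lr_index == 1.0 and vec.ap_index == 1.0

    def test_mirror_symmetric_map_has_zero_lr(self):
        rng = np.random.default_rng(5)
        half = rng.random((17, 8))
        prob = np.concatenate([half, rng.random((17, 1)), half[:, ::-1]], axis=1)
        vec = ap_lr_preference(ego_map_from(prob))
        assert vec.lr_index == pytest.approx(0.0, abs=1e-12)

    def test_lr_antisymmetric_under_mirroring(self):
        rng = np.random.default_rng(6)
        prob = rng.random((17, 17))
        v1 = ap_lr_preference(ego_map_from(prob))
        v2 = ap_lr_preference(ego_map_from(prob[:, ::-1]))
        assert v2.lr_index == pytest.approx(-v1.lr_index)
        assert v2.ap_index == pytest.approx(v1.ap_index)

    def test_all_masked_region_flagged(self):
        prob = np.zeros((17, 17))
        emap = ego_map_from(prob)
        emap.excluded[:, 9:] = True  # right side fully masked
        emap.probability = np.where(emap.excluded, np.nan, emap.probability)
        with pytest.raises(UndefinedResultError):
            ap_lr_preference(emap)
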