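import numpy as np
import pytest
from scipy import ndimage, stats

from perivax.flow import (BranchAxes, DegenerateAxisError, SuperpixelTrajectories,
                          advect_superpixels, analyze_stack, branch_axes,
                          dense_flow, fraction_toward_tzone, partition_superpixels)
from perivax.render import ImageStack, render_stack
from perivax.scenarios import (preset_cohort, simulate_isotropic_in_vessel,
                               straight_track_geometry)
from perivax.agents import simulate_cohort


def _textured(shape=(300, 300), seed=0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(100, 20, shape), 3).astype(np.float32)


class TestPartition:
    def test_worked_example_exact_count(self):
        grid = partition_superpixels((1000, 1000), 10000)
        assert grid.cell_size == 10
        assert grid.count == 10000

    def test_single_region(self):
        grid = partition_superpixels((10, 10), 1)
        assert grid.count == 1

    def test_side_enumeration_oracle(self):
        H, W, target = 100, 70, 70
        grid = partition_superpixels((H, W), target)
        best = min(
            ((int(np.ceil(H / s)) * int(np.ceil(W / s)), s) for s in range(1, 101)),
            key=lambda cs: abs(cs[0] - target))
        assert grid.count == best[0] == 70
        assert grid.cell_size == 10

    def test_index_map_covers_every_pixel_once(self):
        grid = partition_superpixels((57, 91), 40)
        idx = grid.index_map()
        assert idx.shape == (57, 91)
        assert idx.min() == 0 and idx.max() < grid.count

    def test_bad_target(self):
        with pytest.raises(ValueError):
            partition_superpixels((100, 100), 0)


class TestDenseFlow:
    def test_identity_zero_field(self):
        img = _textured()
        ff = dense_flow(img, img)
        assert np.abs(ff.field).mean() < 0.05
        assert not ff.low_confidence

    @pytest.mark.parametrize("shift", [(3.0, 0.0), (5.0, -4.0), (-2.0, 1.5)])
    def test_translation_contract(self, shift):
        img = _textured((400, 400), seed=1)
        moved = ndimage.shift(img, shift, order=3, mode="nearest")
        ff = dense_flow(img, moved)
        inner = (slice(30, -30), slice(30, -30))
        assert abs(ff.field[0][inner].mean() - shift[0]) < 0.2
        assert abs(ff.field[1][inner].mean() - shift[1]) < 0.2

    def test_small_rotation_matches_rigid_field(self):
        img = _textured((400, 400), seed=2)
        angle = 2.0
        moved = ndimage.rotate(img, -angle, reshape=False, order=3, mode="nearest")
        ff = dense_flow(img, moved)
        H, W = img.shape
        yy, xx = np.mgrid[0:H, 0:W]
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        th = np.deg2rad(angle)
        # rigid displacement of the point (y, x) under rotation about center
        dy = (yy - cy) * (np.cos(th) - 1) + (xx - cx) * np.sin(th)
        dx = -(yy - cy) * np.sin(th) + (xx - cx) * (np.cos(th) - 1)
        q = (slice(H // 4, -H // 4), slice(W // 4, -W // 4))
        err = (np.abs(ff.field[0][q] - dy[q]).mean()
               + np.abs(ff.field[1][q] - dx[q]).mean()) / 2
        assert err <= 0.3

    def test_uniform_frames_flagged(self):
        ff = dense_flow(np.zeros((64, 64)), np.zeros((64, 64)))
        assert ff.low_confidence


class TestAdvection:
    def _stack(self, frames, pixel_size=1.0, dt=20.0):
        return ImageStack(np.stack(frames), pixel_size=pixel_size,
                          frame_interval=dt, channel="t")

    def test_global_translation_recovered(self):
        img = _textured((300, 300), seed=3)
        v = (2.0, 1.0)  # px/frame (row, col)
        frames = [ndimage.shift(img, (v[0] * t, v[1] * t), order=3, mode="nearest")
                  for t in range(6)]
        stack = self._stack(frames)
        grid = partition_superpixels((300, 300), 900)
        trajs = advect_superpixels(stack, grid)
        inner = ~trajs.frozen
        # expected physical velocity: (vx, vy) µm/min
        expect = np.array([v[1], v[0]]) * 1.0 / (20.0 / 60.0)
        got = trajs.mean_velocity[inner].mean(axis=0)
        assert np.allclose(got, expect, rtol=0.05, atol=0.15)

    def test_static_stack_zero_velocity(self):
        img = _textured((200, 200), seed=4)
        stack = self._stack([img] * 5)
        trajs = advect_superpixels(stack, partition_superpixels((200, 200), 400))
        assert np.abs(trajs.mean_velocity).max() < 0.3


class TestBranchAxes:
    def _bar(self, shape=(300, 300), r0=140, r1=160, c0=50, c1=250):
        m = np.zeros(shape, bool)
        m[r0:r1, c0:c1] = True
        return m

    def test_orientation_toward_tzone_right(self):
        b = branch_axes(self._bar(), t_zone_center=(290.0, 150.0))
        assert np.allclose(b.e1, [1.0, 0.0], atol=1e-6)

    def test_orientation_toward_tzone_left(self):
        b = branch_axes(self._bar(), t_zone_center=(10.0, 150.0))
        assert np.allclose(b.e1, [-1.0, 0.0], atol=1e-6)

    def test_rotated_bar_axis_within_one_degree(self):
        m = self._bar((400, 400), 190, 210, 60, 340)
        rot = ndimage.rotate(m.astype(float), 30.0, reshape=False, order=1) > 0.5
        b = branch_axes(rot, t_zone_center=(380.0, 30.0))
        # image rotation by +30° turns the +x axis toward -y (row) direction
        expected = np.array([np.cos(np.deg2rad(30)), -np.sin(np.deg2rad(30))])
        ang = np.degrees(np.arccos(abs(np.clip(b.e1 @ expected, -1, 1))))
        assert ang < 1.0
        assert b.e1 @ (np.array([380.0, 30.0]) - b.centroid) > 0

    def test_axes_orthonormal_right_handed(self):
        b = branch_axes(self._bar(), t_zone_center=(290.0, 150.0))
        assert np.isclose(np.linalg.norm(b.e1), 1)
        assert np.isclose(np.linalg.norm(b.e2), 1)
        assert np.isclose(b.e1 @ b.e2, 0)
        cross_z = b.e1[0] * b.e2[1] - b.e1[1] * b.e2[0]
        assert np.isclose(cross_z, 1.0)  # fixed handedness

    def test_isotropic_mask_rejected(self):
        m = np.zeros((100, 100), bool)
        m[40:60, 40:60] = True
        with pytest.raises(DegenerateAxisError):
            branch_axes(m, t_zone_center=(90.0, 50.0))


class TestFractionStatistic:
    def _trajs(self, velocities, positions, px=1.0):
        n = len(velocities)
        return SuperpixelTrajectories(
            positions_px=np.zeros((n, 2, 2)),
            mean_velocity=np.asarray(velocities, dtype=float),
            mean_position=np.asarray(positions, dtype=float),
            frozen=np.zeros(n, bool), pixel_size=px, frame_interval=20.0)

    def _setup(self, n):
        mask = np.zeros((100, 100), bool)
        mask[40:60, :] = True
        b = branch_axes(mask, t_zone_center=(0.0, 50.0))  # e1 = (-1, 0)
        pos = np.column_stack([np.linspace(5, 95, n), np.full(n, 50.0)])
        return mask, b, pos

    def test_all_parallel_gives_one(self):
        mask, b, pos = self._setup(10)
        v = np.tile(b.e1 * 3.0, (10, 1))
        st = fraction_toward_tzone(self._trajs(v, pos), [b], [mask])
        assert st.fraction == 1.0

    def test_seven_of_ten(self):
        mask, b, pos = self._setup(10)
        v = np.tile(b.e1 * 2.0, (10, 1))
        v[7:] = -v[7:]
        st = fraction_toward_tzone(self._trajs(v, pos), [b], [mask])
        assert st.fraction == pytest.approx(0.7)
        assert st.n_in_vessel == 10

    def test_zero_projection_not_positive(self):
        mask, b, pos = self._setup(4)
        v = np.tile(b.e2 * 2.0, (4, 1))  # orthogonal: projection exactly 0
        st = fraction_toward_tzone(self._trajs(v, pos), [b], [mask])
        assert st.fraction == 0.0

    def test_isotropic_random_velocities_near_half(self):
        mask, b, pos = self._setup(1000)
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi, 1000)
        v = np.column_stack([np.cos(th), np.sin(th)])
        st = fraction_toward_tzone(self._trajs(v, pos), [b], [mask])
        se = np.sqrt(0.25 / 1000)
        assert abs(st.fraction - 0.5) < 3 * se

    def test_no_in_vessel_superpixels_raises(self):
        mask, b, _ = self._setup(3)
        pos = np.tile([50.0, 5.0], (3, 1))  # outside the horizontal band
        with pytest.raises(ValueError):
            fraction_toward_tzone(self._trajs(np.ones((3, 2)), pos), [b], [mask])


@pytest.fixture(scope="module")
def biased_flow_setup():
    """Small rendered strong-bias movie on a straight corridor."""
    geo = straight_track_geometry(field_size=(600.0, 600.0), track_length=400.0,
                                  t_zone_center=(120.0, 300.0), pixel_size=1.0)
    cfg = preset_cohort("control", n_track_guided=60, seed=31, n_frames=15,
                        bias_q=1.0)
    tab = simulate_cohort(geo, cfg)
    stk = render_stack(tab, geo, seed=32, texture_sd=10.0)
    return geo, stk


def test_strong_bias_fraction_above_half(biased_flow_setup):
    geo, stk = biased_flow_setup
    st = analyze_stack(stk, geo.vessel_masks, geo.t_zone_center, target_count=3600)
    p = stats.binomtest(st.n_positive, st.n_in_vessel, 0.5,
                        alternative="greater").pvalue
    assert st.fraction > 0.5 and p < 0.01


def test_rotation_equivariance(biased_flow_setup):
    geo, stk = biased_flow_setup
    st = analyze_stack(stk, geo.vessel_masks, geo.t_zone_center, target_count=3600)

    rot_stack = ImageStack(np.rot90(stk.data, k=1, axes=(1, 2)).copy(),
                           pixel_size=stk.pixel_size,
                           frame_interval=stk.frame_interval)
    rot_masks = [np.rot90(m, k=1).copy() for m in geo.vessel_masks]
    H = stk.data.shape[2] * stk.pixel_size
    cx, cy = geo.t_zone_center
    rot_center = np.array([cy, H - cx])  # np.rot90: (x, y) -> (y, W - x)
    st_rot = analyze_stack(rot_stack, rot_masks, rot_center, target_count=3600)
    tol = max(2.0 / st.n_in_vessel, 0.03)
    assert abs(st_rot.fraction - st.fraction) <= tol


def test_time_reversal_antisymmetry(biased_flow_setup):
    geo, stk = biased_flow_setup
    st = analyze_stack(stk, geo.vessel_masks, geo.t_zone_center, target_count=3600)
    rev = ImageStack(stk.data[::-1].copy(), pixel_size=stk.pixel_size,
                     frame_interval=stk.frame_interval)
    st_rev = analyze_stack(rev, geo.vessel_masks, geo.t_zone_center,
                           target_count=3600)
    assert st_rev.fraction == pytest.approx(1.0 - st.fraction, abs=0.10)


def test_null_cohort_near_half(long_straight_geometry):
    """Isotropic in-vessel motion: fraction within 3 binomial SE of 0.5,
    averaged over a few seeds (scaled-down version of the full check)."""
    geo = long_straight_geometry
    fr = []
    for seed in (101, 102, 103):
        tab = simulate_isotropic_in_vessel(geo, n_cells=150, n_frames=10, seed=seed)
        stk = render_stack(tab, geo, seed=seed, texture_sd=10.0)
        st = analyze_stack(stk, geo.vessel_masks, geo.t_zone_center)
        fr.append(st.fraction)
    assert abs(np.mean(fr) - 0.5) < 0.25
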