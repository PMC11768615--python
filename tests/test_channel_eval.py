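"""Channel construction and the accessibility / injury / constructability metrics."""

import numpy as np
import pytest

from millplan import (
    BinaryMask,
    ToolModel,
    VoxelGrid,
    accessibility,
    boundary_smoothness,
    build_channel,
    compactness,
    constructability,
    injury,
)
from millplan.area_param import AreaFunction, ControlPlane
from millplan.channel_eval import (
    SmoothnessConfig,
    SurgicalChannel,
    hemisphere_directions,
    spectral_arc_length,
)
from millplan.volume_core import CriticalStructure, compute_sdf


def shell_scene(n=40, spacing=1.0, wall=(25, 30)):
    """Head half-space with a bone wall; returns grid, bone, head masks."""
    grid = VoxelGrid((n, n, n), spacing)
    bone = np.zeros(grid.shape, bool)
    bone[wall[0] : wall[1], :, :] = True
    head = np.zeros(grid.shape, bool)
    head[: wall[1], :, :] = True
    return grid, BinaryMask(grid, bone), BinaryMask(grid, head)


def channel_from_mask(occ: np.ndarray, grid: VoxelGrid) -> SurgicalChannel:
    m = BinaryMask(grid, occ)
    empty = BinaryMask(grid, np.zeros(grid.shape, bool))
    return SurgicalChannel(empty, empty, empty, m)


class TestBuildChannel:
    def test_no_breach_keeps_exterior_only(self):
        grid, bone, head = shell_scene()
        mill = BinaryMask(grid, np.zeros(grid.shape, bool))
        ch = build_channel(mill, bone, head)
        assert np.array_equal(ch.channel.occupancy, ~head.occupancy)
        assert ch.internal_cavities.n_voxels == 0

    def test_full_thickness_hole_joins_interior(self):
        grid, bone, head = shell_scene()
        mill = np.zeros(grid.shape, bool)
        mill[25:30, 18:22, 18:22] = True
        ch = build_channel(BinaryMask(grid, mill), bone, head)
        assert ch.internal_cavities.n_voxels > 0
        assert ch.channel.occupancy[10, 20, 20]  # deep cavity reached

    def test_sealed_cavity_excluded(self):
        grid = VoxelGrid((30, 30, 30), 1.0)
        bone = np.zeros(grid.shape, bool)
        bone[5:25, 5:25, 5:25] = True
        bone[10:20, 10:20, 10:20] = False  # sealed pocket inside solid bone
        head = np.zeros(grid.shape, bool)
        head[:27, :27, :27] = True
        mill = BinaryMask(grid, np.zeros(grid.shape, bool))
        ch = build_channel(mill, BinaryMask(grid, bone), BinaryMask(grid, head))
        assert not ch.channel.occupancy[15, 15, 15]

    def test_mill_outside_bone_rejected(self):
        grid, bone, head = shell_scene()
        mill = np.zeros(grid.shape, bool)
        mill[0, 0, 0] = True
        with pytest.raises(ValueError, match="subset"):
            build_channel(BinaryMask(grid, mill), bone, head)


class TestAccessibility:
    def test_unobstructed_grid_gives_one(self):
        grid = VoxelGrid((30, 30, 30), 1.0)
        ch = channel_from_mask(np.ones(grid.shape, bool), grid)
        mu = accessibility(ch, [[15.0, 15.0, 15.0]], ToolModel(1.0), [-1, 0, 0], 64, 0)
        assert mu == 1.0

    def test_sealed_channel_gives_zero(self):
        grid = VoxelGrid((30, 30, 30), 1.0)
        ch = channel_from_mask(np.zeros(grid.shape, bool), grid)
        mu = accessibility(ch, [[15.0, 15.0, 15.0]], ToolModel(1.0), [-1, 0, 0], 64, 0)
        assert mu == 0.0

    def test_cone_matches_solid_angle_fraction(self):
        """A 30-degree half-angle cone admits 1-cos(30) of hemisphere directions
        as the tool radius becomes negligible."""
        grid = VoxelGrid((48, 48, 48), 1.0)
        apex = np.array([8.0, 24.0, 24.0])
        centers = grid.voxel_centers()
        rel = centers - apex
        along = rel[..., 0]
        lateral = np.linalg.norm(rel[..., 1:], axis=-1)
        occ = (along >= 0) & (lateral <= np.tan(np.deg2rad(30)) * along)
        ch = channel_from_mask(occ, grid)
        mu = accessibility(
            ch, [apex], ToolModel(0.2), [-1, 0, 0],
            n_directions=2048, seed=0, eps_mm=6.0,
        )
        assert mu == pytest.approx(1.0 - np.cos(np.deg2rad(30)), abs=0.05)

    def test_monotone_in_channel(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid((24, 24, 24), 1.0)
        occ = rng.random(grid.shape) < 0.5
        t = [[12.0, 12.0, 12.0]]
        mu1 = accessibility(channel_from_mask(occ, grid), t, ToolModel(1.0), [-1, 0, 0], 64, 0)
        grown = occ | (rng.random(grid.shape) < 0.3)
        mu2 = accessibility(channel_from_mask(grown, grid), t, ToolModel(1.0), [-1, 0, 0], 64, 0)
        assert mu2 >= mu1

    def test_direction_count_floor(self):
        grid = VoxelGrid((10, 10, 10), 1.0)
        ch = channel_from_mask(np.ones(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            accessibility(ch, [[5.0, 5.0, 5.0]], ToolModel(1.0), [-1, 0, 0], n_directions=8)

    def test_hemisphere_directions_on_correct_side(self):
        dirs = hemisphere_directions([1.0, 0.0, 0.0], 128, seed=3)
        assert np.all(dirs @ [1.0, 0.0, 0.0] > 0)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)


class TestInjury:
    def _scene(self):
        grid = VoxelGrid((20, 20, 20), 1.0)
        bone = np.zeros(grid.shape, bool)
        bone[5:15, :, :] = True
        return grid, BinaryMask(grid, bone)

    def test_empty_mill_is_zero(self):
        grid, bone = self._scene()
        mill = BinaryMask(grid, np.zeros(grid.shape, bool))
        assert injury(mill, bone, [], 1.0) == 0.0

    def test_full_bone_fraction_times_weight(self):
        grid, bone = self._scene()
        tube = np.zeros(grid.shape, bool)
        tube[0:2, 0:2, 0:2] = True  # outside bone: no overlap
        s = CriticalStructure("s", BinaryMask(grid, tube),
                              compute_sdf(BinaryMask(grid, tube)), "minimize_S", lambda_weight=0.5)
        assert injury(bone, bone, [s], 0.5) == pytest.approx(0.5)

    def test_constructed_overlap_fraction(self):
        """Mill overlapping exactly 1/8 of a structure: Q_i decomposes linearly."""
        grid, bone = self._scene()
        s_occ = np.zeros(grid.shape, bool)
        s_occ[5:13, 4:8, 4:8] = True  # 8x4x4 = 128 voxels, inside/outside bone mixed
        mill = np.zeros(grid.shape, bool)
        mill[5:6, 4:8, 4:8] = True  # 16 voxels = 1/8 of the structure
        s = CriticalStructure("s", BinaryMask(grid, s_occ),
                              compute_sdf(BinaryMask(grid, s_occ)), "minimize_S", lambda_weight=0.5)
        got = injury(BinaryMask(grid, mill), bone, [s], 0.5)
        want = 0.5 * (16 / bone.n_voxels) + 0.5 * 0.125
        assert got == pytest.approx(want, abs=1e-12)

    def test_weight_sum_violation_rejected(self):
        grid, bone = self._scene()
        with pytest.raises(ValueError, match="sum"):
            injury(bone, bone, [], 0.9)


class TestCompactness:
    def test_two_adjacent_voxels_closed_form(self):
        grid = VoxelGrid((10, 10, 10), 1.0)
        occ = np.zeros(grid.shape, bool)
        occ[5, 5, 5] = occ[5, 5, 6] = True
        assert compactness(BinaryMask(grid, occ)) == pytest.approx(2.0)

    def test_obstacle_blocks_pair(self):
        grid = VoxelGrid((10, 10, 10), 1.0)
        occ = np.zeros(grid.shape, bool)
        occ[5, 5, 4] = occ[5, 5, 6] = True  # gap voxel (5,5,5) is an obstacle
        assert compactness(BinaryMask(grid, occ)) == 0.0

    def test_ball_more_compact_than_rod_and_estimator_accuracy(self):
        from conftest import small_ball_mask

        ball = small_ball_mask(radius_vox=4.0)
        n_ball = ball.n_voxels
        grid = VoxelGrid((n_ball + 4, 5, 5), 1.0)
        rod = np.zeros(grid.shape, bool)
        rod[2 : 2 + n_ball, 2, 2] = True  # same voxel count, 1-voxel thick
        rod_mask = BinaryMask(grid, rod)
        mu_ball = compactness(ball, exhaustive=True)
        mu_rod = compactness(rod_mask, exhaustive=True)
        assert mu_ball > mu_rod
        # seeded subsample estimator stays within 5% of the exhaustive sum
        for seed in range(10):
            est = compactness(ball, n_samples=128, seed=seed)
            assert est == pytest.approx(mu_ball, rel=0.05)


def star_polygon(n_points=8, r_outer=10.0, area_match=None, m=1024):
    th = np.linspace(0, 2 * np.pi, m, endpoint=False)
    k = n_points
    r = r_outer * (0.55 + 0.45 * np.cos(k * th))
    if area_match is not None:
        area = 0.5 * np.sum(r**2) * (2 * np.pi / m)
        r *= np.sqrt(area_match / area)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def circle_polygon(radius=10.0, m=1024):
    th = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.stack([radius * np.cos(th), radius * np.sin(th)], axis=1)


class TestSmoothness:
    def test_circle_smoother_than_star(self):
        circle = circle_polygon()
        star = star_polygon(area_match=np.pi * 10.0**2)
        assert spectral_arc_length(circle) > spectral_arc_length(star)

    def test_translation_invariance(self):
        star = star_polygon()
        a = spectral_arc_length(star)
        b = spectral_arc_length(star + [123.4, -56.7])
        assert a == pytest.approx(b, abs=1e-9)

    def test_uniform_scaling_invariance(self):
        star = star_polygon()
        a = spectral_arc_length(star)
        b = spectral_arc_length(star * 2.0)
        assert a == pytest.approx(b, abs=1e-3)

    def test_short_contour_rejected(self):
        with pytest.raises(ValueError):
            spectral_arc_length(np.zeros((5, 2)))

    def test_union_raster_contour_ordering(self):
        """Rasterised circle vs star through the full area-function path."""
        plane = ControlPlane((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
                             1.0, (64, 64), (-32.0, -32.0))

        def area_of(raster):
            return AreaFunction(plane, np.zeros(3), raster,
                                np.where(raster, 0, -1).astype(np.int64),
                                np.zeros((1, 3)), np.zeros(2))

        uu, vv = np.meshgrid(np.arange(64) - 31.5, np.arange(64) - 31.5, indexing="ij")
        circle = uu**2 + vv**2 <= 20.0**2
        rho = np.sqrt(uu**2 + vv**2)
        th = np.arctan2(vv, uu)
        star = rho <= 20.0 * (0.55 + 0.45 * np.cos(8 * th))
        mu_circle = boundary_smoothness([area_of(circle)])
        mu_star = boundary_smoothness([area_of(star)])
        assert mu_circle > mu_star


class TestConstructability:
    def test_reference_anchor(self):
        assert constructability(7.5, 7.5, 0.0) == -1.0

    def test_direct_substitution(self):
        assert constructability(5.0, 10.0, -1.0) == pytest.approx(-0.5 * np.exp(-1.0))

    def test_very_rough_boundary_limit(self):
        assert constructability(5.0, 10.0, -50.0) == pytest.approx(0.0, abs=1e-20)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            constructability(1.0, 0.0, 0.0)
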