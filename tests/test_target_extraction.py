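"""Effective-target cascade T0 -> T4: normals, filters, contour, downsampling."""

import numpy as np
import pytest

from millplan import BinaryMask, ToolModel, VoxelGrid, compute_sdf
from millplan.area_param import ControlPlane
from millplan.target_extraction import (
    TargetStage,
    downsample_contour,
    estimate_surface_normals,
    extract_ordered_contour,
    filter_accessible,
    filter_orientation,
    surface_voxels,
    thin_entries,
)
from millplan.volume_core import CriticalStructure

from conftest import small_ball_mask


def unit_plane() -> ControlPlane:
    return ControlPlane(
        origin_mm=(50.0, 0.0, 0.0),
        u_axis=(0.0, 1.0, 0.0),
        v_axis=(0.0, 0.0, 1.0),
        pixel_mm=1.0,
        shape=(64, 64),
        uv0=(-32.0, -32.0),
    )


class TestNormals:
    def test_ball_normals_radial(self):
        mask = small_ball_mask(radius_vox=7.0)
        idx, normals = estimate_surface_normals(mask)
        c = (np.asarray(mask.grid.shape) - 1) / 2.0
        radial = idx - c
        radial = radial / np.linalg.norm(radial, axis=1)[:, None]
        cosang = np.einsum("ij,ij->i", normals, radial)
        frac = np.mean(cosang > np.cos(np.deg2rad(10)))
        assert frac >= 0.95

    def test_box_face_normal_axis_aligned(self):
        grid = VoxelGrid((20, 20, 20), 1.0)
        occ = np.zeros(grid.shape, bool)
        occ[5:14, 5:14, 5:14] = True  # odd extent: voxel 9 is the exact face centre
        idx, normals = estimate_surface_normals(BinaryMask(grid, occ))
        sel = np.all(idx == [13, 9, 9], axis=1)
        assert np.allclose(normals[sel][0], [1.0, 0.0, 0.0], atol=1e-9)

    def test_ellipsoid_normals_match_gradient(self):
        grid = VoxelGrid((40, 40, 40), 1.0)
        c = np.array([19.5, 19.5, 19.5])
        semi = np.array([12.0, 8.0, 6.0])
        centers = grid.voxel_centers()
        occ = np.sum(((centers - c) / semi) ** 2, axis=-1) <= 1.0
        idx, normals = estimate_surface_normals(BinaryMask(grid, occ))
        pts = grid.index_to_world(idx)
        analytic = 2 * (pts - c) / semi**2
        analytic /= np.linalg.norm(analytic, axis=1)[:, None]
        ang = np.rad2deg(np.arccos(np.clip(np.einsum("ij,ij->i", normals, analytic), -1, 1)))
        assert np.median(ang) <= 15.0

    def test_single_voxel_rejected(self):
        grid = VoxelGrid((8, 8, 8), 1.0)
        occ = np.zeros(grid.shape, bool)
        occ[4, 4, 4] = True
        with pytest.raises(ValueError):
            estimate_surface_normals(BinaryMask(grid, occ))


class TestOrientationFilter:
    def test_back_facing_points_excluded(self):
        mask = small_ball_mask(radius_vox=6.0)
        idx, normals = estimate_surface_normals(mask)
        c = (np.asarray(mask.grid.shape) - 1) / 2.0
        entries = np.array([c + [20.0, 0.0, 0.0]])  # all entries on +x side
        t1 = filter_orientation(mask, idx, normals, entries)
        # retained normals point toward the entries
        dirs = entries[0] - t1.points_mm
        dots = np.einsum("ij,ij->i", dirs, t1.normals)
        assert np.all(dots > 0)

    def test_all_equal_counts_is_error(self):
        """With one entry seeing every point equally, no r_t strictly beats the mean."""
        grid = VoxelGrid((16, 16, 16), 1.0)
        occ = np.zeros(grid.shape, bool)
        occ[6:10, 6:10, 6:8] = True
        mask = BinaryMask(grid, occ)
        idx = surface_voxels(mask)
        normals = np.tile([1.0, 0.0, 0.0], (len(idx), 1))  # all face +x identically
        entries = np.array([[40.0, 8.0, 8.0]])
        with pytest.raises(ValueError, match="orientation filter"):
            filter_orientation(mask, idx, normals, entries)

    def test_hemisphere_concentration(self):
        """Entry cloud on one side retains the facing hemisphere of the ball."""
        mask = small_ball_mask(radius_vox=7.0)
        idx, normals = estimate_surface_normals(mask)
        c = (np.asarray(mask.grid.shape) - 1) / 2.0
        rng = np.random.default_rng(3)
        entries = c + [25.0, 0.0, 0.0] + rng.uniform(-6, 6, (40, 3)) * [0, 1, 1]
        t1 = filter_orientation(mask, idx, normals, entries)
        mean_dir = (entries.mean(axis=0) - c)
        mean_dir /= np.linalg.norm(mean_dir)
        frac = np.mean(t1.normals @ mean_dir > 0)
        assert frac >= 0.80
        # brute-force recount: every retained r_t beats both thresholds
        tk = entries[None, :, :] - t1.points_mm[:, None, :]
        r = (np.einsum("mkd,md->mk", tk, t1.normals) > 0).sum(axis=1)
        assert np.array_equal(r, t1.r_counts)


class TestAccessibilityFilter:
    def _ball_t1(self):
        mask = small_ball_mask(radius_vox=6.0, pad=10)
        idx, normals = estimate_surface_normals(mask)
        c = (np.asarray(mask.grid.shape) - 1) / 2.0
        rng = np.random.default_rng(0)
        entries = c + [14.0, 0.0, 0.0] + rng.uniform(-5, 5, (60, 3)) * [0, 1, 1]
        t1 = filter_orientation(mask, idx, normals, entries)
        return mask, t1, entries

    def test_no_structures_passthrough(self):
        mask, t1, entries = self._ball_t1()
        t2 = filter_accessible(t1, entries, [], ToolModel(1.0))
        assert np.array_equal(t2.points_mm, t1.points_mm)

    def test_occluding_wall_matches_exhaustive_oracle(self):
        mask, t1, entries = self._ball_t1()
        grid = mask.grid
        c = (np.asarray(grid.shape) - 1) / 2.0
        wall = np.zeros(grid.shape, bool)
        # half-plane wall between entries and the ball, occluding z > centre
        wall[int(c[0]) + 8, :, int(c[2]) + 2 :] = True
        ws = CriticalStructure("wall", BinaryMask(grid, wall),
                               compute_sdf(BinaryMask(grid, wall)), "intact_H", d_risk_mm=0.5)
        tool = ToolModel(1.0)
        t2 = filter_accessible(t1, entries, [ws], tool)
        assert len(t2.points_mm) < len(t1.points_mm)
        # exhaustive oracle over the full entry set
        from millplan.max_milling import feasibility_matrix

        feas_full = feasibility_matrix(entries, t1.points_mm, [ws], tool)
        oracle_keep = feas_full.any(axis=0)
        got_keep = np.array([
            any(np.allclose(p, q) for q in t2.points_mm) for p in t1.points_mm
        ])
        agreement = np.mean(got_keep == oracle_keep)
        assert agreement >= 0.95

    def test_single_cell_thinning(self):
        entries = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.5, 0.5, 0.5]])
        thin = thin_entries(entries, ToolModel(5.0))  # 2r = 10 swallows everything
        assert len(thin) == 1
        assert np.allclose(thin[0], entries[0])


class TestContourAndDownsample:
    def _cap_stage(self, half_angle_deg=60.0, radius_vox=8.0):
        mask = small_ball_mask(radius_vox=radius_vox, pad=4)
        idx = surface_voxels(mask)
        c = (np.asarray(mask.grid.shape) - 1) / 2.0
        rel = idx - c
        cosang = rel[:, 0] / np.linalg.norm(rel, axis=1)
        keep = cosang >= np.cos(np.deg2rad(half_angle_deg))
        t2 = TargetStage("T2", mask.grid.index_to_world(idx[keep]), idx[keep])
        return mask, t2, c

    def test_cap_rim_is_closed_clockwise_loop(self):
        mask, t2, c = self._cap_stage()
        t3 = extract_ordered_contour(t2, mask, unit_plane())
        uv = unit_plane().world_to_uv(t3.points_mm)
        ctr = uv.mean(axis=0)
        ang = np.unwrap(np.arctan2(uv[:, 1] - ctr[1], uv[:, 0] - ctr[0]))
        assert np.all(np.diff(ang) <= 1e-9)  # monotone decreasing = clockwise
        # loop closes: first and last are near-neighbours on the rim
        gap = np.linalg.norm(t3.points_mm[0] - t3.points_mm[-1])
        steps = np.linalg.norm(np.diff(t3.points_mm, axis=0), axis=1)
        assert gap <= steps.max() + mask.grid.spacing_mm

    def test_rim_circumference_matches_analytic(self):
        half_angle = 60.0
        radius = 8.0
        mask, t2, c = self._cap_stage(half_angle, radius)
        t3 = extract_ordered_contour(t2, mask, unit_plane())
        closed = np.vstack([t3.points_mm, t3.points_mm[0]])
        length = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        analytic = 2 * np.pi * radius * np.sin(np.deg2rad(half_angle))
        assert length == pytest.approx(analytic, rel=0.10)

    def test_too_few_boundary_points_rejected(self):
        mask = small_ball_mask(radius_vox=5.0)
        idx = surface_voxels(mask)
        t2 = TargetStage("T2", mask.grid.index_to_world(idx[:1]), idx[:1])
        with pytest.raises(ValueError):
            extract_ordered_contour(t2, mask, unit_plane())

    def test_downsample_count_and_spacing(self):
        """A circle loop of length 10r downsamples to ~10 points at interval r."""
        r = 1.5
        circ = 10 * r
        rad = circ / (2 * np.pi)
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.stack([np.zeros_like(th), rad * np.cos(th), rad * np.sin(th)], axis=1)
        t3 = TargetStage("T3", pts, np.zeros((len(pts), 3), int))
        t4 = downsample_contour(t3, ToolModel(r))
        assert abs(len(t4.points_mm) - 10) <= 1
        d = np.linalg.norm(np.diff(t4.points_mm, axis=0), axis=1)
        assert np.all(d >= r * 0.95) and np.all(d <= 2 * r)

    def test_interval_larger_than_loop_keeps_one_point(self):
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.stack([np.zeros_like(th), np.cos(th), np.sin(th)], axis=1)
        t3 = TargetStage("T3", pts, np.zeros((len(pts), 3), int))
        t4 = downsample_contour(t3, ToolModel(100.0))
        assert len(t4.points_mm) == 1


class TestStageMonotonicity:
    def test_stages_nested_and_t4_feasible(self, setup):
        stages = setup.stages
        sets = {
            name: {tuple(i) for i in stages[name].indices} for name in ("T1", "T2", "T3", "T4")
        }
        assert sets["T4"] <= sets["T3"] <= sets["T2"] <= sets["T1"]
        # every T4 point keeps at least one feasible entry under the full K
        from millplan.max_milling import feasibility_matrix

        feas = feasibility_matrix(
            setup.entries, stages["T4"].points_mm, setup.phantom.intact_structures, setup.tool
        )
        assert feas.any(axis=0).all()

    def test_t4_count_envelope(self, setup):
        assert 10 <= len(setup.stages["T4"].points_mm) <= 40
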