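"""Shared fixtures: the default phantom scene and its prepared planning stages.

Heavy objects are session-scoped so the full suite builds the scene once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from millplan import (
    BinaryMask,
    TerminationConfig,
    ToolModel,
    VoxelGrid,
    find_entry_candidates,
    generate_max_area,
    generate_phantom,
)
from millplan.area_param import MillingReconstructor, make_control_plane, project_entries
from millplan.max_milling import feasibility_matrix
from millplan.phantom import Phantom
from millplan.target_extraction import extract_targets


@dataclass
class PlanningSetup:
    phantom: Phantom
    tool: ToolModel
    centroid: np.ndarray
    entries: np.ndarray
    plane: object
    stages: dict
    targets: np.ndarray  # T4 points
    feasibility: np.ndarray
    max_area: object
    max_area_bone: BinaryMask
    areas: list
    recon: MillingReconstructor
    kept: list


@pytest.fixture(scope="session")
def phantom_default() -> Phantom:
    return generate_phantom()


@pytest.fixture(scope="session")
def setup(phantom_default: Phantom) -> PlanningSetup:
    ph = phantom_default
    tool = ToolModel(ph.spec.tool_radius_mm)
    centroid = ph.target.world_points().mean(axis=0)
    entries = find_entry_candidates(ph.bone, centroid, ph.spec.approach_axis, 14.0)
    plane = make_control_plane(centroid, entries, ph.spec.approach_axis, ph.grid.spacing_mm)
    stages = extract_targets(ph.target, entries, ph.intact_structures, tool, plane)
    targets = stages["T4"].points_mm
    feas = feasibility_matrix(entries, targets, ph.intact_structures, tool)
    max_area = generate_max_area(
        targets, entries, ph.intact_structures, tool, ph.grid,
        TerminationConfig(), ph.spec.approach_axis, feasibility=feas,
    )
    kept = sorted(max_area.per_target_entries)
    areas = [
        project_entries(targets[ti], max_area.per_target_entries[ti], plane, tool)
        for ti in kept
    ]
    recon = MillingReconstructor(areas, tool, ph.grid)
    max_area_bone = BinaryMask(
        ph.grid, max_area.union_mask.occupancy & ph.bone.occupancy
    )
    return PlanningSetup(
        ph, tool, centroid, entries, plane, stages, targets, feas,
        max_area, max_area_bone, areas, recon, kept,
    )


def small_ball_mask(radius_vox: float = 5.0, spacing: float = 1.0, pad: int = 3) -> BinaryMask:
    n = int(2 * (radius_vox + pad)) + 1
    grid = VoxelGrid((n, n, n), spacing)
    c = (n - 1) / 2.0 * spacing
    centers = grid.voxel_centers()
    occ = np.linalg.norm(centers - c, axis=-1) <= radius_vox * spacing
    return BinaryMask(grid, occ)
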