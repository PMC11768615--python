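"""Maximum permissible milling area as a union of feasible tool cylinders.

The surgical tool is modelled as a cylinder of radius r.  A trajectory from
an entry point k on the skull surface to a target point t is feasible when
the tool axis keeps a margin of ``r + d_risk`` from every structure that must
remain intact.  The maximum milling area is the voxel union of all feasible
cylinders, organised per target so that the feasible entry set K(t) of each
target can later be parameterised.

An early-termination rule truncates the per-target entry sweep once fresh
entries stop contributing volume: the normalised gain of entry k is

    G_t(k) = (new voxels * voxel volume) / (|kt| * pi r^2)

and the sweep stops after G_t stays below a threshold (default 5e-4) for a
configurable number of consecutive feasible entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_core import (
    BinaryMask,
    CriticalStructure,
    SignedDistanceField,
    VoxelGrid,
    compute_sdf,
    sdf_min_along_segment,
    segment_points,
)


@dataclass(frozen=True)
class ToolModel:
    """Cylindrical tool; the radius is the single dimension used everywhere."""

    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tool radius must be positive")


@dataclass(frozen=True)
class TerminationConfig:
    enabled: bool = True
    threshold: float = 5e-4
    window: int = 25


@dataclass
class TrajectorySet:
    entries: np.ndarray  # (K,3) world mm
    targets: np.ndarray  # (T,3) world mm
    feasibility: np.ndarray  # (K,T) bool


@dataclass
class MaxMillingArea:
    per_target_entries: dict[int, np.ndarray]  # t index -> feasible entry points (M,3)
    per_target_masks: dict[int, np.ndarray]  # t index -> bool volume
    union_mask: BinaryMask
    dropped_targets: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Entry candidates
# ---------------------------------------------------------------------------


def find_entry_candidates(
    bone: BinaryMask,
    target_centroid: np.ndarray,
    approach_axis: np.ndarray,
    max_offset_mm: float,
    bone_sdf: SignedDistanceField | None = None,
) -> np.ndarray:
    """Outer-surface bone voxels facing the approach, near the target axis.

    A bone surface voxel is a candidate when its outward normal (gradient of
    the bone SDF) has positive dot product with the outward approach
    direction, and its lateral offset from the line through the target
    centroid along ``approach_axis`` is at most ``max_offset_mm``.  Returned
    in deterministic lexicographic index order.
    """
    if not bone.occupancy.any():
        raise ValueError("bone mask is empty")
    a = np.asarray(approach_axis, dtype=float)
    a = a / np.linalg.norm(a)
    target_centroid = np.asarray(target_centroid, dtype=float)

    occ = bone.occupancy
    surf = occ & ~ndimage.binary_erosion(occ, structure=ndimage.generate_binary_structure(3, 1))
    if bone_sdf is None:
        bone_sdf = compute_sdf(bone)
    grads = np.stack(np.gradient(bone_sdf.values, bone.grid.spacing_mm), axis=-1)

    idx = np.argwhere(surf)
    pts = bone.grid.index_to_world(idx)
    normals = grads[surf]
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    normals = normals / norms[:, None]

    facing = normals @ (-a) > 0.0
    rel = pts - target_centroid
    lateral = rel - np.outer(rel @ a, a)
    near = np.linalg.norm(lateral, axis=1) <= max_offset_mm
    keep = facing & near
    if not np.any(keep):
        raise ValueError("no entry candidates")
    return pts[keep]


# ---------------------------------------------------------------------------
# Trajectory feasibility
# ---------------------------------------------------------------------------


def trajectory_feasible(
    k: np.ndarray,
    t: np.ndarray,
    structures: list[CriticalStructure],
    tool: ToolModel,
    step_mm: float | None = None,
) -> bool:
    """True iff the tool axis [k,t] keeps ``r + d_risk`` from every intact structure."""
    k = np.asarray(k, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.allclose(k, t):
        raise ValueError("entry and target coincide")
    for s in structures:
        if s.role != "intact_H":
            raise ValueError(f"structure {s.name!r} is not intact_H")
        if sdf_min_along_segment(s.sdf, k, t, step_mm) <= tool.radius_mm + s.d_risk_mm:
            return False
    return True


def feasibility_matrix(
    entries: np.ndarray,
    targets: np.ndarray,
    structures: list[CriticalStructure],
    tool: ToolModel,
    step_mm: float | None = None,
    chunk: int = 64,
) -> np.ndarray:
    """Vectorised (K,T) feasibility table equivalent to ``trajectory_feasible``."""
    entries = np.atleast_2d(np.asarray(entries, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    nk, nt = len(entries), len(targets)
    feas = np.ones((nk, nt), dtype=bool)
    if not structures:
        return feas
    for s in structures:
        if s.role != "intact_H":
            raise ValueError(f"structure {s.name!r} is not intact_H")
    grid = structures[0].sdf.grid
    if step_mm is None:
        step_mm = grid.spacing_mm / 2.0
    for t0 in range(0, nt, chunk):
        tgt = targets[t0 : t0 + chunk]  # (c,3)
        diff = tgt[None, :, :] - entries[:, None, :]  # (K,c,3)
        lengths = np.linalg.norm(diff, axis=-1)
        n_samp = max(int(np.ceil(lengths.max() / step_mm)), 1) + 1
        svals = np.linspace(0.0, 1.0, n_samp)
        # points: (K,c,n,3)
        pts = entries[:, None, None, :] + diff[:, :, None, :] * svals[None, None, :, None]
        flat = pts.reshape(-1, 3)
        for s in structures:
            idx = s.sdf.grid.world_to_index(flat)
            vals = ndimage.map_coordinates(s.sdf.values, idx.T, order=1, mode="nearest")
            dmin = vals.reshape(nk, len(tgt), n_samp).min(axis=-1)
            feas[:, t0 : t0 + chunk] &= dmin > tool.radius_mm + s.d_risk_mm
    return feas


# ---------------------------------------------------------------------------
# Cylinder rasterization
# ---------------------------------------------------------------------------


def _cylinder_flat_indices(k: np.ndarray, t: np.ndarray, radius: float, grid: VoxelGrid) -> np.ndarray:
    """Flat voxel indices whose centres lie in the open finite cylinder k->t."""
    k = np.asarray(k, dtype=float)
    t = np.asarray(t, dtype=float)
    sp = grid.spacing_mm
    lo = np.floor((np.minimum(k, t) - radius - grid.origin) / sp).astype(int)
    hi = np.ceil((np.maximum(k, t) + radius - grid.origin) / sp).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid.shape) - 1)
    if np.any(hi < lo):
        return np.empty(0, dtype=np.int64)
    axes = [grid.origin[d] + np.arange(lo[d], hi[d] + 1) * sp for d in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xs, ys, zs], axis=-1)
    kt = t - k
    rel_k = pts - k
    rel_t = pts - t
    along = np.einsum("...d,d->...", rel_k, kt)
    inside = (along > 0.0) & (np.einsum("...d,d->...", rel_t, -kt) > 0.0)
    cross = np.linalg.norm(np.cross(rel_k, kt / np.linalg.norm(kt)), axis=-1)
    inside &= cross < radius
    ii, jj, kk = np.nonzero(inside)
    return np.ravel_multi_index(
        (ii + lo[0], jj + lo[1], kk + lo[2]), grid.shape
    ).astype(np.int64)


def rasterize_cylinder(k: np.ndarray, t: np.ndarray, tool: ToolModel, grid: VoxelGrid) -> BinaryMask:
    """Voxelise the open finite cylinder of radius r between k and t.

    A voxel is occupied iff its centre is within r of the line through k and
    t and strictly between the two end planes (caps excluded).
    """
    if np.allclose(k, t):
        raise ValueError("entry and target coincide")
    occ = np.zeros(grid.shape, dtype=bool)
    flat = _cylinder_flat_indices(np.asarray(k, float), np.asarray(t, float), tool.radius_mm, grid)
    occ.ravel()[flat] = True
    return BinaryMask(grid, occ)


def early_termination_gain(
    prev_mask_voxels: int,
    new_mask_voxels: int,
    k: np.ndarray,
    t: np.ndarray,
    tool: ToolModel,
    voxel_volume: float,
) -> float:
    """Normalised volume contribution of one entry: added volume over |kt| * pi r^2."""
    if new_mask_voxels < prev_mask_voxels:
        raise ValueError("voxel count cannot decrease")
    length = float(np.linalg.norm(np.asarray(t, float) - np.asarray(k, float)))
    return (new_mask_voxels - prev_mask_voxels) * voxel_volume / (
        length * np.pi * tool.radius_mm**2
    )


# ---------------------------------------------------------------------------
# Maximum milling area generation
# ---------------------------------------------------------------------------


def entry_traversal_order(entries: np.ndarray, targets: np.ndarray, approach_axis: np.ndarray) -> np.ndarray:
    """Deterministic near-to-far entry sweep.

    Entries are ordered by increasing distance from the entry nearest the
    line through the target centroid along the approach axis, with
    lexicographic world-coordinate tie-breaks.
    """
    entries = np.asarray(entries, dtype=float)
    a = np.asarray(approach_axis, dtype=float)
    a = a / np.linalg.norm(a)
    centroid = np.asarray(targets, dtype=float).mean(axis=0)
    rel = entries - centroid
    lateral = np.linalg.norm(rel - np.outer(rel @ a, a), axis=1)
    seed_idx = int(np.lexsort((entries[:, 2], entries[:, 1], entries[:, 0], lateral))[0])
    d = np.linalg.norm(entries - entries[seed_idx], axis=1)
    return np.lexsort((entries[:, 2], entries[:, 1], entries[:, 0], d))


def generate_max_area(
    targets: np.ndarray,
    entries: np.ndarray,
    structures: list[CriticalStructure],
    tool: ToolModel,
    grid: VoxelGrid,
    termination: TerminationConfig = TerminationConfig(),
    approach_axis: np.ndarray = (-1.0, 0.0, 0.0),
    feasibility: np.ndarray | None = None,
) -> MaxMillingArea:
    """Accumulate feasible cylinders per target into the maximum milling area.

    Entries are swept in the deterministic near-to-far order; infeasible
    entries are skipped without advancing the early-termination counter
    (only realised, feasible contributions count as "consistently low gain").
    Targets with no feasible entry are dropped with a warning; an all-empty
    result is an error.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    entries = np.atleast_2d(np.asarray(entries, dtype=float))
    if feasibility is None:
        feasibility = feasibility_matrix(entries, targets, structures, tool)
    order = entry_traversal_order(entries, targets, approach_axis)

    vox_vol = grid.voxel_volume_mm3
    union = np.zeros(grid.shape, dtype=bool)
    per_entries: dict[int, np.ndarray] = {}
    per_masks: dict[int, np.ndarray] = {}
    dropped: list[int] = []

    for ti in range(len(targets)):
        t = targets[ti]
        mask_t = np.zeros(grid.shape, dtype=bool)
        flat_mask = mask_t.ravel()
        kept: list[np.ndarray] = []
        count = 0
        low_streak = 0
        for ki in order:
            if not feasibility[ki, ti]:
                continue
            k = entries[ki]
            flat = _cylinder_flat_indices(k, t, tool.radius_mm, grid)
            new_count = count + int(np.count_nonzero(~flat_mask[flat]))
            gain = early_termination_gain(count, new_count, k, t, tool, vox_vol)
            flat_mask[flat] = True
            count = new_count
            kept.append(k)
            if termination.enabled:
                if gain < termination.threshold:
                    low_streak += 1
                    if low_streak >= termination.window:
                        break
                else:
                    low_streak = 0
        if not kept:
            warnings.warn(f"target {ti} has no feasible entry; dropped", stacklevel=2)
            dropped.append(ti)
            continue
        per_entries[ti] = np.asarray(kept)
        per_masks[ti] = mask_t
        union |= mask_t

    if not per_masks:
        raise ValueError("no target has a feasible entry; cannot build milling area")
    return MaxMillingArea(per_entries, per_masks, BinaryMask(grid, union), dropped)
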