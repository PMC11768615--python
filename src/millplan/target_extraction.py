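"""Effective-target extraction: reduce the target surface to an ordered rim.

Only the entry-facing, reachable part of the target surface matters for
channel planning, and adjacent tool trajectories overlap, so the dense
voxel surface is reduced in four stages:

  T0  all surface voxels of the target mask
  T1  surface points oriented toward enough entry candidates
  T2  T1 points with at least one feasible trajectory (entries thinned to a
      2r grid, first success wins)
  T3  the ordered closed boundary contour of T2 on the target surface
  T4  T3 downsampled at arc-length interval r (adjacent trajectories overlap)

Keeping ~tens of rim points caps the optimisation at a few hundred
parameters while the reconstructed channel still exposes the whole face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .area_param import ControlPlane
from .max_milling import ToolModel, feasibility_matrix
from .volume_core import BinaryMask, CriticalStructure, compute_sdf


@dataclass
class TargetStage:
    stage: str
    points_mm: np.ndarray  # (M,3), ordered for T3/T4
    indices: np.ndarray  # (M,3) voxel indices
    normals: np.ndarray | None = None
    r_counts: np.ndarray | None = None  # entry-facing counts (stage T1)


def surface_voxels(target: BinaryMask) -> np.ndarray:
    """Indices of 6-connectivity surface voxels, lexicographic order."""
    occ = target.occupancy
    core = ndimage.binary_erosion(occ, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(occ & ~core)


def estimate_surface_normals(target: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit normals at surface voxels from the target SDF gradient.

    Returns (surface indices, unit normals).  The SDF increases outward, so
    its gradient points out of the structure; a one-voxel Gaussian smooth
    removes the lattice quantisation of the raw distance transform before
    differentiation.
    """
    if target.n_voxels < 2:
        raise ValueError("target too small for normal estimation")
    sdf = compute_sdf(target)
    smoothed = ndimage.gaussian_filter(sdf.values, sigma=1.0)
    grads = np.stack(np.gradient(smoothed, target.grid.spacing_mm), axis=-1)
    idx = surface_voxels(target)
    n = grads[idx[:, 0], idx[:, 1], idx[:, 2]]
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate surface: zero SDF gradient at a surface voxel")
    return idx, n / norms[:, None]


def filter_orientation(
    target: BinaryMask,
    surface_idx: np.ndarray,
    normals: np.ndarray,
    entries: np.ndarray,
) -> TargetStage:
    """Stage T1: keep surface points facing enough entry candidates.

    r_t counts entries within 90 degrees of the outward normal; a point is
    kept iff r_t strictly exceeds both the mean count and 5% of |K|.
    """
    entries = np.atleast_2d(np.asarray(entries, float))
    if len(entries) == 0:
        raise ValueError("no entries supplied")
    pts = target.grid.index_to_world(surface_idx)
    tk = entries[None, :, :] - pts[:, None, :]  # (M,K,3)
    facing = np.einsum("mkd,md->mk", tk, normals) > 0.0
    r = facing.sum(axis=1)
    keep = (r > r.mean()) & (r > 0.05 * len(entries))
    if not np.any(keep):
        raise ValueError("orientation filter removed every target point")
    return TargetStage("T1", pts[keep], surface_idx[keep], normals[keep], r[keep])


def thin_entries(entries: np.ndarray, tool: ToolModel) -> np.ndarray:
    """Representative entries on a 2r world-space grid (lowest index per cell)."""
    entries = np.atleast_2d(np.asarray(entries, float))
    cells = np.floor(entries / (2.0 * tool.radius_mm)).astype(int)
    _, first = np.unique(cells, axis=0, return_index=True)
    return entries[np.sort(first)]


def filter_accessible(
    t1: TargetStage,
    entries: np.ndarray,
    structures: list[CriticalStructure],
    tool: ToolModel,
) -> TargetStage:
    """Stage T2: keep T1 points with at least one feasible thinned entry."""
    thin = thin_entries(entries, tool)
    feas = feasibility_matrix(thin, t1.points_mm, structures, tool)
    keep = feas.any(axis=0)
    if not np.any(keep):
        raise ValueError("no target point is reachable under the intact-structure constraints")
    return TargetStage(
        "T2",
        t1.points_mm[keep],
        t1.indices[keep],
        None if t1.normals is None else t1.normals[keep],
    )


def _largest_component(idx: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a voxel index set (boolean on idx)."""
    key = {tuple(i): n for n, i in enumerate(idx)}
    visited = np.zeros(len(idx), dtype=bool)
    best: list[int] = []
    offsets = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    )
    for start in range(len(idx)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = key.get(tuple(idx[cur] + off))
                if nb is not None and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        if len(comp) > len(best):
            best = comp
    mask = np.zeros(len(idx), dtype=bool)
    mask[best] = True
    return mask


def extract_ordered_contour(
    t2: TargetStage,
    target: BinaryMask,
    plane: ControlPlane,
) -> TargetStage:
    """Stage T3: clockwise-ordered boundary of the reachable surface patch.

    Boundary points are T2 points adjacent (26-connectivity) to a surface
    voxel outside T2.  They are ordered clockwise by the polar angle of their
    projection onto the control plane about the projected centroid, looking
    along the approach direction.  If T2 fragments, the largest connected
    component is used (with a warning).
    """
    comp = _largest_component(t2.indices)
    if not comp.all():
        warnings.warn("reachable surface patch is fragmented; using largest component",
                      stacklevel=2)
    idx = t2.indices[comp]
    pts = t2.points_mm[comp]

    surf_all = surface_voxels(target)
    surf_set = {tuple(i) for i in surf_all}
    in_t2 = {tuple(i) for i in idx}
    offsets = [
        (a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)
    ]
    boundary = []
    for n, i in enumerate(idx):
        for off in offsets:
            nb = (i[0] + off[0], i[1] + off[1], i[2] + off[2])
            if nb in surf_set and nb not in in_t2:
                boundary.append(n)
                break
    if len(boundary) < 3:
        raise ValueError("fewer than 3 boundary points; cannot form a contour")
    b = np.asarray(boundary)
    uv = plane.world_to_uv(pts[b])
    c = uv.mean(axis=0)
    ang = np.arctan2(uv[:, 1] - c[1], uv[:, 0] - c[0])
    # clockwise when viewed along the approach direction (against the plane normal)
    order = np.argsort(-ang, kind="stable")
    return TargetStage("T3", pts[b][order], idx[b][order])


def downsample_contour(t3: TargetStage, tool: ToolModel) -> TargetStage:
    """Stage T4: greedy arc-length resampling of the closed loop at interval r.

    The first point is always kept; a point is emitted whenever the walked
    arc length since the last emission reaches r, so consecutive samples are
    between r and r plus one segment apart (tool trajectories overlap).
    """
    pts = t3.points_mm
    keep = [0]
    acc = 0.0
    for i in range(1, len(pts)):
        acc += float(np.linalg.norm(pts[i] - pts[i - 1]))
        if acc >= tool.radius_mm:
            keep.append(i)
            acc = 0.0
    k = np.asarray(keep)
    return TargetStage("T4", pts[k], t3.indices[k])


def extract_targets(
    target: BinaryMask,
    entries: np.ndarray,
    structures: list[CriticalStructure],
    tool: ToolModel,
    plane: ControlPlane,
) -> dict[str, TargetStage]:
    """Run the full T0->T4 cascade; returns all stages keyed by name."""
    surf_idx, normals = estimate_surface_normals(target)
    t0 = TargetStage("T0", target.grid.index_to_world(surf_idx), surf_idx, normals)
    t1 = filter_orientation(target, surf_idx, normals, entries)
    t2 = filter_accessible(t1, entries, structures, tool)
    t3 = extract_ordered_contour(t2, target, plane)
    t4 = downsample_contour(t3, tool)
    return {"T0": t0, "T1": t1, "T2": t2, "T3": t3, "T4": t4}


def export_stages_csv(stages: dict[str, TargetStage], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stage", "idx", "r_mm", "a_mm", "s_mm"])
        for name, st in stages.items():
            for i, p in enumerate(st.points_mm):
                w.writerow([name, i, f"{p[0]:.4f}", f"{p[1]:.4f}", f"{p[2]:.4f}"])
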