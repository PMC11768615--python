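"""Parameterization of per-target feasible-entry regions.

For each retained target point t, the feasible entries K(t) are projected
along the rays t->k onto a control plane parallel to the anatomical A-S
plane, giving a 2-D area function B_t.  A periodic control function
sigma_t(theta) with N spline knots, values in (0,1], radially shrinks B_t
about its (frozen) mass centre; the subset restriction guarantees the
deformed area never leaves B_t, so every surviving ray stays feasible.  The
milling volume is reconstructed as the union of tool cylinders C(k(g), t)
over all surviving raster cells g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from .max_milling import ToolModel, _cylinder_flat_indices
from .volume_core import BinaryMask, VoxelGrid

SIGMA_FLOOR = 1e-3  # keeps sigma strictly positive, as the open interval (0,1] requires


# ---------------------------------------------------------------------------
# Control plane
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlPlane:
    """Raster plane parallel to the A-S plane on the approach side.

    ``normal = u_axis x v_axis`` points along the approach-side R direction;
    all area functions of one plan share a single plane (and raster window)
    so their union is well defined.
    """

    origin_mm: tuple[float, float, float]
    u_axis: tuple[float, float, float]
    v_axis: tuple[float, float, float]
    pixel_mm: float
    shape: tuple[int, int]
    uv0: tuple[float, float]  # in-plane (u,v) mm of raster cell (0,0) centre

    def __post_init__(self) -> None:
        u = np.asarray(self.u_axis, float)
        v = np.asarray(self.v_axis, float)
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9 or abs(u @ v) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthonormal")

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, float)

    @property
    def u(self) -> np.ndarray:
        return np.asarray(self.u_axis, float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.v_axis, float)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def world_to_uv(self, pts: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(pts) - self.origin
        return np.stack([rel @ self.u, rel @ self.v], axis=1)

    def uv_to_cell(self, uv: np.ndarray) -> np.ndarray:
        return np.round((np.atleast_2d(uv) - np.asarray(self.uv0)) / self.pixel_mm).astype(int)

    def cell_to_uv(self, cells: np.ndarray) -> np.ndarray:
        return np.asarray(self.uv0) + np.atleast_2d(cells) * self.pixel_mm


def make_control_plane(
    target_centroid: np.ndarray,
    entries: np.ndarray,
    approach_axis: np.ndarray,
    pixel_mm: float,
    margin_mm: float = 4.0,
) -> ControlPlane:
    """Place the shared control plane just beyond the outermost entry.

    The plane normal points against the approach direction (outward), its
    origin sits at the target centroid projected onto the plane, and the
    raster window covers the projected entry footprint plus a margin.
    """
    a = np.asarray(approach_axis, float)
    a = a / np.linalg.norm(a)
    normal = -a  # outward
    # in-plane axes spanning A and S when normal is +/-R
    ref = np.array([0.0, 1.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = ref - (ref @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    entries = np.atleast_2d(np.asarray(entries, float))
    centroid = np.asarray(target_centroid, float)
    d = float(np.max((entries - centroid) @ normal)) + pixel_mm
    origin = centroid + d * normal
    rel = entries - origin
    uu = rel @ u
    vv = rel @ v
    lo = np.array([uu.min(), vv.min()]) - margin_mm
    hi = np.array([uu.max(), vv.max()]) + margin_mm
    shape = tuple(np.ceil((hi - lo) / pixel_mm).astype(int) + 1)
    # swap so normal == u x v
    if np.allclose(np.cross(u, v), -normal):
        u, v = v, u
    return ControlPlane(tuple(origin), tuple(u), tuple(v), float(pixel_mm), shape, tuple(lo))


# ---------------------------------------------------------------------------
# Area function
# ---------------------------------------------------------------------------


@dataclass
class AreaFunction:
    """Entry-selection raster B_t on the control plane for one target."""

    plane: ControlPlane
    target_mm: np.ndarray
    raster: np.ndarray  # bool (nu, nv)
    entry_map: np.ndarray  # int (nu, nv): row into `entries`, -1 where empty
    entries: np.ndarray  # (M,3) feasible entry points backing this area
    mass_center_uv: np.ndarray  # frozen polar centre, in-plane mm

    def occupied_cells(self) -> np.ndarray:
        return np.argwhere(self.raster)

    @property
    def area_mm2(self) -> float:
        return float(self.raster.sum()) * self.plane.pixel_mm**2


def close_area(raster: np.ndarray, tool: ToolModel, pixel_mm: float) -> np.ndarray:
    """Morphological closing with a kernel of physical half-width r.

    A square footprint is used: unlike a round element, it bridges isolated
    projected entries separated by sub-r gaps, which is the point of the
    operation (the projected K(t) samples are pixel-sparse).  The output is
    always a superset of the input.
    """
    rad = max(int(np.ceil(tool.radius_mm / pixel_mm)), 1)
    closed = ndimage.binary_closing(raster, structure=np.ones((2 * rad + 1,) * 2, bool))
    return closed | raster


def project_entries(
    t: np.ndarray,
    entries_t: np.ndarray,
    plane: ControlPlane,
    tool: ToolModel,
) -> AreaFunction:
    """Project feasible entries of one target onto the control plane.

    Each entry k is carried along the ray t->k to its plane intersection g;
    the raster cell containing g is set and remembers its generating entry
    (nearest-to-plane wins when several entries share a cell).  The raster is
    then morphologically closed; cells added by closing inherit the entry of
    their nearest projected cell, keeping every cell backed by a feasibility-
    checked trajectory.
    """
    t = np.asarray(t, float)
    entries_t = np.atleast_2d(np.asarray(entries_t, float))
    normal = plane.normal
    plane_off = (plane.origin - t) @ normal

    raster = np.zeros(plane.shape, dtype=bool)
    entry_map = np.full(plane.shape, -1, dtype=np.int64)
    best_dist = np.full(plane.shape, np.inf)

    dirs = entries_t - t
    denom = dirs @ normal
    ok = np.abs(denom) > 1e-6
    n_skipped = int(np.count_nonzero(~ok))
    if n_skipped:
        import warnings

        warnings.warn(f"{n_skipped} entries with rays parallel to the control plane skipped",
                      stacklevel=2)
    s = np.where(ok, plane_off / np.where(ok, denom, 1.0), 0.0)
    g = t + dirs * s[:, None]
    uv = plane.world_to_uv(g)
    cells = plane.uv_to_cell(uv)
    plane_dist = np.abs((entries_t - plane.origin) @ normal)

    for i in np.nonzero(ok)[0]:
        ci, cj = cells[i]
        if not (0 <= ci < plane.shape[0] and 0 <= cj < plane.shape[1]):
            continue
        raster[ci, cj] = True
        if plane_dist[i] < best_dist[ci, cj]:
            best_dist[ci, cj] = plane_dist[i]
            entry_map[ci, cj] = i
    if not raster.any():
        raise ValueError("no entries project into the control-plane window")

    closed = close_area(raster, tool, plane.pixel_mm)
    # closing-added cells borrow the nearest original cell's entry
    _, (ni, nj) = ndimage.distance_transform_edt(~raster, return_indices=True)
    added = closed & ~raster
    entry_map[added] = entry_map[ni[added], nj[added]]

    cells_occ = np.argwhere(closed)
    uv_occ = plane.cell_to_uv(cells_occ)
    mass_center = uv_occ.mean(axis=0)
    return AreaFunction(plane, t, closed, entry_map, entries_t, mass_center)


# ---------------------------------------------------------------------------
# Control function
# ---------------------------------------------------------------------------


@dataclass
class ControlFunction:
    """Periodic cubic spline sigma(theta) in (0,1] with N uniform knots."""

    sigmas: np.ndarray  # (N,) knot values in (0,1]

    def __post_init__(self) -> None:
        self.sigmas = np.clip(np.asarray(self.sigmas, float), SIGMA_FLOOR, 1.0)
        n = len(self.sigmas)
        theta = np.arange(n + 1) / n * 2.0 * np.pi
        vals = np.append(self.sigmas, self.sigmas[0])
        self._spline = CubicSpline(theta, vals, bc_type="periodic")

    @property
    def n_points(self) -> int:
        return len(self.sigmas)

    @property
    def knot_thetas(self) -> np.ndarray:
        return np.arange(self.n_points) / self.n_points * 2.0 * np.pi


def evaluate_sigma(cf: ControlFunction, theta: np.ndarray | float) -> np.ndarray | float:
    """Spline value at theta (2*pi periodic), clipped into (0,1]."""
    th = np.mod(np.asarray(theta, float), 2.0 * np.pi)
    out = np.clip(cf._spline(th), SIGMA_FLOOR, 1.0)
    return float(out) if np.isscalar(theta) else out


# ---------------------------------------------------------------------------
# Deformation and reconstruction
# ---------------------------------------------------------------------------


def deform_area(B: AreaFunction, cf: ControlFunction) -> AreaFunction:
    """Radial deformation: keep cell (rho,theta) iff B holds at (rho/sigma(theta), theta).

    The polar centre is the frozen mass centre of the undeformed area.  The
    second factor of the deformation (the subset restriction) means the
    output is always a subset of B, so spatial feasibility is preserved.
    """
    cells = np.argwhere(B.raster)
    if len(cells) == 0:
        return B
    uv = B.plane.cell_to_uv(cells)
    rel = uv - B.mass_center_uv
    rho = np.linalg.norm(rel, axis=1)
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
    sig = evaluate_sigma(cf, theta)
    look_uv = B.mass_center_uv + rel / np.asarray(sig)[:, None]
    look_cells = B.plane.uv_to_cell(look_uv)
    inb = (
        (look_cells[:, 0] >= 0)
        & (look_cells[:, 0] < B.raster.shape[0])
        & (look_cells[:, 1] >= 0)
        & (look_cells[:, 1] < B.raster.shape[1])
    )
    keep = np.zeros(len(cells), dtype=bool)
    keep[inb] = B.raster[look_cells[inb, 0], look_cells[inb, 1]]
    keep |= rho < B.plane.pixel_mm / 2.0  # the centre cell is invariant under scaling
    out = np.zeros_like(B.raster)
    out[cells[keep, 0], cells[keep, 1]] = True
    return AreaFunction(B.plane, B.target_mm, out, B.entry_map, B.entries, B.mass_center_uv)


@dataclass
class ParameterSet:
    """One sigma row of N knots per retained target; all values in (0,1]."""

    values: np.ndarray  # (n_targets, n_knots)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if np.any(self.values <= 0.0) or np.any(self.values > 1.0):
            raise ValueError("parameters must lie in (0,1]")

    @classmethod
    def ones(cls, n_targets: int, n_knots: int) -> "ParameterSet":
        return cls(np.ones((n_targets, n_knots)))


class MillingReconstructor:
    """Parameter vector -> milling volume, with per-(target, entry) cylinder cache.

    The cache makes optimisation-loop reconstruction cheap: each feasible
    (k(g), t) cylinder is voxelised once; a reconstruction is then a union of
    cached voxel index sets selected by the deformed area functions.
    """

    def __init__(self, areas: list[AreaFunction], tool: ToolModel, grid: VoxelGrid):
        self.areas = areas
        self.tool = tool
        self.grid = grid
        self._cache: list[dict[int, np.ndarray]] = [dict() for _ in areas]

    @property
    def n_targets(self) -> int:
        return len(self.areas)

    def _cylinder(self, area_idx: int, entry_idx: int) -> np.ndarray:
        cache = self._cache[area_idx]
        if entry_idx not in cache:
            B = self.areas[area_idx]
            cache[entry_idx] = _cylinder_flat_indices(
                B.entries[entry_idx], B.target_mm, self.tool.radius_mm, self.grid
            )
        return cache[entry_idx]

    def reconstruct(self, params: ParameterSet | np.ndarray) -> BinaryMask:
        if not isinstance(params, ParameterSet):
            params = ParameterSet(params)
        if params.values.shape[0] != self.n_targets:
            raise ValueError("parameter row count must equal the number of areas")
        occ = np.zeros(self.grid.shape, dtype=bool)
        flat = occ.ravel()
        any_cell = False
        for ai, (B, row) in enumerate(zip(self.areas, params.values)):
            deformed = deform_area(B, ControlFunction(row))
            cells = np.argwhere(deformed.raster)
            if len(cells) == 0:
                continue
            any_cell = True
            entry_ids = np.unique(deformed.entry_map[cells[:, 0], cells[:, 1]])
            for ei in entry_ids[entry_ids >= 0]:
                flat[self._cylinder(ai, int(ei))] = True
        if not any_cell:
            raise ValueError("plan vanished: all areas deformed to empty")
        return BinaryMask(self.grid, occ)

    def deformed_areas(self, params: ParameterSet | np.ndarray) -> list[AreaFunction]:
        if not isinstance(params, ParameterSet):
            params = ParameterSet(params)
        return [deform_area(B, ControlFunction(row)) for B, row in zip(self.areas, params.values)]


def reconstruct_milling(
    params: ParameterSet | np.ndarray,
    areas: list[AreaFunction],
    tool: ToolModel,
    grid: VoxelGrid,
) -> BinaryMask:
    """Union of tool cylinders selected by the deformed area functions."""
    return MillingReconstructor(areas, tool, grid).reconstruct(params)
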