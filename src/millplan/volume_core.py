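"""Voxel-lattice data model shared by every planning stage.

All volumes live on an isotropic lattice in RAS millimetre coordinates with a
voxel-centre convention: the world position of integer index ``i`` is
``origin + i * spacing``.  Axis order is fixed as (R, A, S) so index axis 0 is
Right, 1 is Anterior, 2 is Superior.

The module provides the signed distance fields (negative inside a structure,
positive outside) that back all safety-distance queries, isotropic
resampling, and SVD-based landmark rigid alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# Lattice and volume containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel lattice in RAS mm, voxel-centre convention."""

    shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm) ** 3

    @property
    def half_diagonal_mm(self) -> float:
        """Half of the voxel body diagonal — the lattice quantisation bound."""
        return 0.5 * float(self.spacing_mm) * np.sqrt(3.0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional index coordinates of world points (no rounding)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing_mm

    def contains_index(self, idx: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hi = np.asarray(self.shape, dtype=float) - 1
        return np.all((idx >= -tol) & (idx <= hi + tol), axis=1)

    def voxel_centers(self) -> np.ndarray:
        """(Nx,Ny,Nz,3) array of world coordinates of all voxel centres."""
        axes = [self.origin[d] + np.arange(self.shape[d]) * self.spacing_mm for d in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _check_same_grid(a: "VoxelGrid", b: "VoxelGrid") -> None:
    if a.shape != b.shape or abs(a.spacing_mm - b.spacing_mm) > 1e-9 or np.any(
        np.abs(a.origin - b.origin) > 1e-6
    ):
        raise ValueError("volumes do not share the same voxel grid")


@dataclass
class BinaryMask:
    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise ValueError("occupancy shape does not match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def world_points(self) -> np.ndarray:
        """(N,3) world coordinates of occupied voxel centres, lexicographic order."""
        idx = np.argwhere(self.occupancy)
        return self.grid.index_to_world(idx)


@dataclass
class SignedDistanceField:
    """Scalar field in mm: negative inside the structure, positive outside."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid shape")

    def sample(self, points_mm: np.ndarray, mode: Literal["linear", "nearest"] = "linear") -> np.ndarray:
        """Interpolated field values at world points; points must be in bounds."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.grid.world_to_index(pts)
        inside = self.grid.contains_index(idx)
        if not np.all(inside):
            bad = pts[~inside][0]
            raise ValueError(
                f"query point {bad} lies outside the grid; pad the grid before querying"
            )
        order = 1 if mode == "linear" else 0
        return ndimage.map_coordinates(self.values, idx.T, order=order, mode="nearest")


Role = Literal["intact_H", "minimize_S"]


@dataclass
class CriticalStructure:
    """A named anatomical constraint with its role in planning.

    ``intact_H`` structures (sinus dura, facial nerve, vessels, ossicles...)
    must never be approached closer than ``d_risk_mm`` by the tool surface.
    ``minimize_S`` structures (scala vestibuli...) may be damaged, with the
    damaged fraction penalised by ``lambda_weight``.
    """

    name: str
    mask: BinaryMask
    sdf: SignedDistanceField
    role: Role
    d_risk_mm: float | None = None
    lambda_weight: float | None = None

    def __post_init__(self) -> None:
        _check_same_grid(self.mask.grid, self.sdf.grid)
        if self.role == "intact_H":
            if self.d_risk_mm is None or self.d_risk_mm < 0:
                raise ValueError(f"intact structure {self.name!r} needs d_risk_mm >= 0")
        elif self.role == "minimize_S":
            if self.lambda_weight is None or not (0.0 <= self.lambda_weight <= 1.0):
                raise ValueError(f"minimize structure {self.name!r} needs lambda_weight in [0,1]")
        else:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class LandmarkSet:
    names: list[str]
    points_mm: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))
        if len(self.names) != len(set(self.names)):
            raise ValueError("landmark names must be unique")
        if len(self.names) != self.points_mm.shape[0]:
            raise ValueError("names and points length mismatch")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resample_isotropic(volume: BinaryMask | SignedDistanceField, new_spacing_mm: float):
    """Resample a mask (nearest-neighbour) or scalar field (trilinear).

    The output grid covers the same world extent as the input; extents are
    aligned at the outer voxel faces so content keeps its world position
    within one output voxel.
    """
    if new_spacing_mm <= 0:
        raise ValueError("new_spacing_mm must be positive")
    grid = volume.grid
    old = grid.spacing_mm
    extent = np.asarray(grid.shape, dtype=float) * old
    new_shape = np.maximum(np.round(extent / new_spacing_mm).astype(int), 1)
    # outer face of voxel 0 is at origin - spacing/2; keep it fixed
    new_origin = grid.origin - old / 2.0 + new_spacing_mm / 2.0
    new_grid = VoxelGrid(tuple(new_shape), float(new_spacing_mm), tuple(new_origin))

    axes = [
        (new_grid.origin[d] + np.arange(new_shape[d]) * new_spacing_mm - grid.origin[d]) / old
        for d in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")

    if isinstance(volume, BinaryMask):
        out = ndimage.map_coordinates(
            volume.occupancy.astype(np.uint8), coords, order=0, mode="constant", cval=0
        )
        return BinaryMask(new_grid, out.astype(bool))
    out = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
    return SignedDistanceField(new_grid, out)


def compute_sdf(mask: BinaryMask) -> SignedDistanceField:
    """Signed distance field of a binary mask, in mm.

    Outside voxels carry the distance to the nearest occupied voxel centre,
    inside voxels minus the distance to the nearest background voxel centre,
    so the sign flips exactly at the mask boundary.
    """
    occ = mask.occupancy
    if not occ.any():
        raise ValueError("no surface: mask is empty")
    if occ.all():
        raise ValueError("no surface: mask fills the whole grid")
    sp = mask.grid.spacing_mm
    dist_out = ndimage.distance_transform_edt(~occ, sampling=sp)
    dist_in = ndimage.distance_transform_edt(occ, sampling=sp)
    return SignedDistanceField(mask.grid, dist_out - dist_in)


def segment_points(p0: np.ndarray, p1: np.ndarray, step_mm: float) -> np.ndarray:
    """Inclusive sample points along [p0,p1] spaced at most step_mm apart."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step_mm)), 1) + 1
    s = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1.0 - s) + p1[None, :] * s


def sdf_min_along_segment(
    sdf: SignedDistanceField,
    p0: np.ndarray,
    p1: np.ndarray,
    step_mm: float | None = None,
    mode: Literal["linear", "nearest"] = "linear",
) -> float:
    """Minimum structure distance along a straight tool trajectory.

    Samples the signed distance field along [p0, p1] at a spacing of at most
    ``step_mm`` (default: half the voxel spacing) and returns the minimum.
    Negative values mean the segment pierces the structure.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("degenerate segment: p0 == p1")
    if step_mm is None:
        step_mm = sdf.grid.spacing_mm / 2.0
    pts = segment_points(p0, p1, step_mm)
    return float(np.min(sdf.sample(pts, mode=mode)))


@dataclass(frozen=True)
class RigidTransform:
    """World-space rigid transform x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_mm: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.rms_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rigid_align_landmarks(source: LandmarkSet, dest: LandmarkSet) -> RigidTransform:
    """Least-squares rigid alignment of named landmarks (Kabsch / SVD).

    Landmarks are matched by name; at least three non-collinear common
    landmarks are required.  The returned rotation is always proper
    (determinant +1, reflections corrected).
    """
    common = [n for n in source.names if n in dest.names]
    if len(common) < 3:
        raise ValueError("need at least 3 common landmarks")
    src = np.array([source.points_mm[source.names.index(n)] for n in common])
    dst = np.array([dest.points_mm[dest.names.index(n)] for n in common])
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    # collinear configurations leave a rotation axis unconstrained
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise ValueError("landmarks are collinear; rotation is under-determined")
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = dst.mean(axis=0) - rot @ src.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((src @ rot.T + trans - dst) ** 2, axis=1))))
    return RigidTransform(rot, trans, rms)


# ---------------------------------------------------------------------------
# File I/O: NIfTI-1 volumes and landmark CSVs
# ---------------------------------------------------------------------------

_AXIS_NAMES = ("R", "A", "S")


def _grid_from_affine(affine: np.ndarray, shape: Sequence[int], tol: float = 1e-3) -> VoxelGrid:
    lin = affine[:3, :3]
    spacings = np.linalg.norm(lin, axis=0)
    cosines = lin / spacings
    for j in range(3):
        for i in range(3):
            if i != j and abs(cosines[i, j]) > tol:
                raise ValueError(
                    f"NIfTI affine is not axis-aligned: axis {_AXIS_NAMES[j]} has "
                    f"off-diagonal direction cosine {cosines[i, j]:.4f}"
                )
        if cosines[j, j] < 0:
            raise ValueError(
                f"NIfTI affine axis {_AXIS_NAMES[j]} is flipped; reorient to RAS first"
            )
    if np.ptp(spacings) > tol:
        raise ValueError(f"anisotropic spacing {spacings}; resample to isotropic first")
    return VoxelGrid(tuple(int(s) for s in shape), float(spacings.mean()), tuple(affine[:3, 3]))


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.spacing_mm
    aff[:3, 3] = grid.origin
    return aff


def read_nifti_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return BinaryMask(grid, np.asarray(img.dataobj) > 0.5)


def read_nifti_labels(path) -> tuple[VoxelGrid, np.ndarray]:
    """Read an integer label volume; returns (grid, labels)."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return grid, np.asarray(img.dataobj).astype(np.int32)


def write_nifti(volume: BinaryMask | SignedDistanceField, path) -> None:
    if isinstance(volume, BinaryMask):
        data = volume.occupancy.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine_from_grid(volume.grid)), str(path))


def read_landmarks_csv(path) -> LandmarkSet:
    names: list[str] = []
    pts: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"name", "r_mm", "a_mm", "s_mm"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValueError("landmark CSV must have header name,r_mm,a_mm,s_mm")
        for row in reader:
            names.append(row["name"])
            pts.append([float(row["r_mm"]), float(row["a_mm"]), float(row["s_mm"])])
    return LandmarkSet(names, np.asarray(pts))


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "r_mm", "a_mm", "s_mm"])
        for name, p in zip(landmarks.names, landmarks.points_mm):
            writer.writerow([name, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])
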