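"""Synthetic temporal-bone planning scene with closed-form geometry.

The phantom stands in for a clinical CT study: a bone slab of varying
thickness (the mastoid cortex), an ellipsoidal deep target (the tumour),
tube-shaped nerve/vessel structures and a sheet-shaped sinus structure
flanking the feasible corridor, plus one small tube of role ``minimize_S``
(a scala-like duct) placed so the maximum milling area clips it — giving the
optimizer a genuine injury trade-off.  Every shape is echoed verbatim in a
manifest so tests can build analytic distance oracles against the same
geometry the voxel pipeline sees.

All phantom data is synthetic; no clinical volume is emulated beyond the
constraint topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .volume_core import (
    BinaryMask,
    CriticalStructure,
    SignedDistanceField,
    VoxelGrid,
    compute_sdf,
)

# ---------------------------------------------------------------------------
# Shape primitives (all coordinates RAS mm)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Capsule:
    """Tube with hemispherical caps: all points within `radius` of a segment."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    kind: str = "capsule"


@dataclass(frozen=True)
class SheetBox:
    """Axis-aligned box; thin boxes model dural sheets."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    kind: str = "sheet_box"


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    kind: str = "ellipsoid"


Shape = Capsule | SheetBox | Ellipsoid


def _seg_seg_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3-D segments (standard clamped solver)."""
    p0, p1, q0, q1 = (np.asarray(x, dtype=float) for x in (p0, p1, q0, q1))
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest_p = p0 + s * d1
    closest_q = q0 + t * d2
    return float(np.linalg.norm(closest_p - closest_q))


def _point_box_signed(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Signed distance of a point to a box surface (negative inside)."""
    c = (lo + hi) / 2.0
    h = (hi - lo) / 2.0
    q = np.abs(p - c) - h
    outside = float(np.linalg.norm(np.maximum(q, 0.0)))
    inside = float(min(np.max(q), 0.0))
    return outside + inside


_ELLIPSOID_CLOUD_N = 20000


def _ellipsoid_surface_cloud(center, semi_axes, n=_ELLIPSOID_CLOUD_N) -> np.ndarray:
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    unit = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return np.asarray(center) + unit * np.asarray(semi_axes)


def analytic_min_distance(shape: Shape, p0, p1) -> float:
    """Closed-form minimum signed distance between segment [p0,p1] and a shape surface.

    Exact for capsules and boxes (the point-to-shape signed distance is convex
    along the segment, so a bounded 1-D minimisation converges to machine
    precision); the ellipsoid falls back to a dense Fibonacci surface cloud
    (documented accuracy about 0.05 mm at default density and phantom scale).
    Negative values indicate penetration.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if isinstance(shape, Capsule):
        return _seg_seg_distance(p0, p1, shape.p0, shape.p1) - shape.radius
    if isinstance(shape, SheetBox):
        lo = np.asarray(shape.lo, dtype=float)
        hi = np.asarray(shape.hi, dtype=float)

        def f(s: float) -> float:
            return _point_box_signed(p0 + s * (p1 - p0), lo, hi)

        res = minimize_scalar(f, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        return float(min(res.fun, f(0.0), f(1.0)))
    if isinstance(shape, Ellipsoid):
        cloud = _ellipsoid_surface_cloud(shape.center, shape.semi_axes)
        tree = cKDTree(cloud)
        s = np.linspace(0.0, 1.0, 400)
        pts = p0[None] * (1 - s[:, None]) + p1[None] * s[:, None]
        d, _ = tree.query(pts)
        k = int(np.argmin(d))
        lo_s, hi_s = max(s[k] - 0.005, 0.0), min(s[k] + 0.005, 1.0)
        s2 = np.linspace(lo_s, hi_s, 200)
        pts2 = p0[None] * (1 - s2[:, None]) + p1[None] * s2[:, None]
        d2, _ = tree.query(pts2)
        dist = float(min(d.min(), d2.min()))
        # sign: penetration if any sample lies inside the ellipsoid
        rel = (pts - np.asarray(shape.center)) / np.asarray(shape.semi_axes)
        if np.any(np.sum(rel**2, axis=1) < 1.0):
            return -dist
        return dist
    raise ValueError(f"unsupported shape kind {shape!r}")


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureSpec:
    name: str
    shape: Shape
    role: Literal["intact_H", "minimize_S"]
    d_risk_mm: float | None = None
    lambda_weight: float | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic planning scene.

    Defaults define the standard test scene at 1.0 mm spacing: a 64 mm cube,
    an 8±2 mm-thick bone slab whose outer face lies at R = 44 mm, a deep
    ellipsoidal target, two intact tubes and one intact sheet flanking a
    6 mm-radius clear corridor along −R, and one scala-like minimize-S tube
    grazing the corridor so milling plans trade injury against access.
    """

    seed: int = 0
    spacing_mm: float = 1.0
    extent_mm: float = 64.0
    tool_radius_mm: float = 1.5

    # bone slab along R: outer face fixed, inner face sinusoidally modulated
    slab_outer_r: float = 44.0
    slab_inner_r: float = 36.0
    slab_modulation_amp_mm: float = 2.0
    slab_modulation_period_mm: float = 24.0

    head_outer_r: float = 44.0  # head region: everything at R <= this

    target: Ellipsoid = Ellipsoid((18.0, 32.0, 32.0), (5.0, 7.0, 6.0))

    corridor_axis: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (18.0, 32.0, 32.0),
        (44.0, 32.0, 32.0),
    )
    corridor_radius_mm: float = 6.0

    structures: tuple[StructureSpec, ...] = (
        StructureSpec(
            "facial_nerve",
            Capsule((26.0, 18.0, 12.0), (26.0, 18.0, 52.0), 1.5),
            "intact_H",
            d_risk_mm=2.5,
        ),
        StructureSpec(
            "vessel",
            Capsule((26.0, 46.0, 12.0), (26.0, 46.0, 52.0), 2.0),
            "intact_H",
            d_risk_mm=0.5,
        ),
        StructureSpec(
            "sinus_sheet",
            SheetBox((16.0, 20.0, 16.0), (40.0, 44.0, 18.0)),
            "intact_H",
            d_risk_mm=1.5,
        ),
        # scala-like bony duct embedded in the slab, grazing the edge of the
        # milling fan so the maximum area clips a small fraction of it
        StructureSpec(
            "scala",
            Capsule((39.0, 22.0, 46.0), (39.0, 42.0, 46.0), 1.5),
            "minimize_S",
            lambda_weight=0.5,
        ),
    )

    @property
    def approach_axis(self) -> np.ndarray:
        """Unit vector pointing from the skull surface toward the target (−R)."""
        return np.array([-1.0, 0.0, 0.0])


@dataclass
class Phantom:
    spec: PhantomSpec
    grid: VoxelGrid
    bone: BinaryMask
    target: BinaryMask
    head_region: BinaryMask
    structures: list[CriticalStructure]
    manifest: dict

    @property
    def intact_structures(self) -> list[CriticalStructure]:
        return [s for s in self.structures if s.role == "intact_H"]

    @property
    def minimize_structures(self) -> list[CriticalStructure]:
        return [s for s in self.structures if s.role == "minimize_S"]


def _rasterize_shape(shape: Shape, centers: np.ndarray) -> np.ndarray:
    x = centers[..., 0]
    if isinstance(shape, Capsule):
        p0 = np.asarray(shape.p0)
        p1 = np.asarray(shape.p1)
        axis = p1 - p0
        denom = float(axis @ axis)
        rel = centers - p0
        t = np.clip(np.einsum("...k,k->...", rel, axis) / denom, 0.0, 1.0)
        closest = p0 + t[..., None] * axis
        return np.linalg.norm(centers - closest, axis=-1) <= shape.radius
    if isinstance(shape, SheetBox):
        lo = np.asarray(shape.lo)
        hi = np.asarray(shape.hi)
        return np.all((centers >= lo) & (centers <= hi), axis=-1)
    if isinstance(shape, Ellipsoid):
        rel = (centers - np.asarray(shape.center)) / np.asarray(shape.semi_axes)
        return np.sum(rel**2, axis=-1) <= 1.0
    raise ValueError(f"unsupported shape {shape!r}")


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Rasterise the scene onto one grid and validate the corridor guarantee.

    The corridor capsule must clear every intact structure by more than
    ``tool_radius + d_risk`` (checked analytically), so at least one feasible
    end-to-end trajectory always exists.  Identical specs give bitwise
    identical volumes.
    """
    spec = spec or PhantomSpec()
    # corridor clearance validation against the analytic shapes
    c0, c1 = spec.corridor_axis
    for s in spec.structures:
        if s.role != "intact_H":
            continue
        d = analytic_min_distance(s.shape, c0, c1)
        needed = spec.corridor_radius_mm + spec.tool_radius_mm + float(s.d_risk_mm)
        if d <= needed:
            raise ValueError(
                f"corridor clearance violated by structure {s.name!r}: "
                f"distance {d:.2f} mm <= required {needed:.2f} mm"
            )

    n = int(round(spec.extent_mm / spec.spacing_mm))
    grid = VoxelGrid((n, n, n), spec.spacing_mm, (0.0, 0.0, 0.0))
    centers = grid.voxel_centers()
    x, y, z = centers[..., 0], centers[..., 1], centers[..., 2]

    rng = np.random.default_rng(spec.seed)
    phase_y, phase_z = rng.uniform(0.0, 2.0 * np.pi, size=2)
    inner = spec.slab_inner_r + spec.slab_modulation_amp_mm * np.sin(
        2.0 * np.pi * y / spec.slab_modulation_period_mm + phase_y
    ) * np.sin(2.0 * np.pi * z / spec.slab_modulation_period_mm + phase_z)
    bone = (x >= inner) & (x <= spec.slab_outer_r)
    head = x <= spec.head_outer_r
    target_occ = _rasterize_shape(spec.target, centers)

    bone_mask = BinaryMask(grid, bone)
    target_mask = BinaryMask(grid, target_occ)
    head_mask = BinaryMask(grid, head)

    structures: list[CriticalStructure] = []
    for s in spec.structures:
        occ = _rasterize_shape(s.shape, centers)
        m = BinaryMask(grid, occ)
        structures.append(
            CriticalStructure(
                name=s.name,
                mask=m,
                sdf=compute_sdf(m),
                role=s.role,
                d_risk_mm=s.d_risk_mm,
                lambda_weight=s.lambda_weight,
            )
        )
        if s.role == "intact_H" and np.any(occ & target_occ):
            raise ValueError(f"intact structure {s.name!r} intersects the target")

    manifest = {
        "seed": spec.seed,
        "spacing_mm": spec.spacing_mm,
        "extent_mm": spec.extent_mm,
        "tool_radius_mm": spec.tool_radius_mm,
        "slab": {
            "outer_r": spec.slab_outer_r,
            "inner_r": spec.slab_inner_r,
            "modulation_amp_mm": spec.slab_modulation_amp_mm,
            "modulation_period_mm": spec.slab_modulation_period_mm,
            "phase_y": float(phase_y),
            "phase_z": float(phase_z),
        },
        "target": asdict(spec.target),
        "corridor": {"axis": spec.corridor_axis, "radius_mm": spec.corridor_radius_mm},
        "structures": [asdict(s) for s in spec.structures],
    }
    return Phantom(spec, grid, bone_mask, target_mask, head_mask, structures, manifest)
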