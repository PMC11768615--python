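"""Quantitative evaluation of a candidate milling volume.

Three planning objectives are derived from the surgical channel (exterior
space + connected internal cavities + milled bone):

* accessibility mu_a / Q_a — fraction of approach-side directions along
  which a tool capsule from each target reaches the grid boundary inside the
  channel, averaged over targets; Q_a = -mu_a.
* injury Q_i — weighted damaged-volume fractions of bone and minimize-S
  structures, weights summing to one.
* constructability Q_c — combines global spatial compactness mu_gsc (an
  obstacle-aware sum of inverse pairwise distances, normalised by its value
  on the maximum milling area) with the spectral-arc-length smoothness
  mu_sa of the union boundary contour on the control plane:
  Q_c = -(mu_gsc / mu_gsc_ref) * exp(mu_sa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .area_param import AreaFunction
from .max_milling import ToolModel
from .volume_core import BinaryMask, CriticalStructure


@dataclass
class SurgicalChannel:
    mill: BinaryMask
    internal_cavities: BinaryMask
    external_space: BinaryMask
    channel: BinaryMask


@dataclass
class EvaluationResult:
    mu_a: float
    q_a: float
    q_i: float
    mu_gsc: float
    mu_gsc_ref: float
    mu_sa: float
    q_c: float

    def as_dict(self) -> dict:
        return {
            "mu_a": self.mu_a,
            "Q_a": self.q_a,
            "Q_i": self.q_i,
            "mu_gsc": self.mu_gsc,
            "mu_gsc_ref": self.mu_gsc_ref,
            "mu_sa": self.mu_sa,
            "Q_c": self.q_c,
        }


# ---------------------------------------------------------------------------
# Channel construction
# ---------------------------------------------------------------------------


def build_channel(mill: BinaryMask, bone: BinaryMask, head_region: BinaryMask) -> SurgicalChannel:
    """Assemble the surgical channel: exterior, milled bone, connected cavities.

    Internal cavities are non-bone voxels inside the head that connect to the
    milled volume or the exterior through free (non-bone or milled) voxels
    with 6-connectivity; sealed cavities stay out of the channel.
    """
    if np.any(mill.occupancy & ~bone.occupancy):
        raise ValueError("milling mask must be a subset of the bone mask")
    ex = ~head_region.occupancy
    cavities = head_region.occupancy & ~bone.occupancy
    free = ex | mill.occupancy | cavities
    labels, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(3, 1))
    open_labels = np.unique(labels[ex | mill.occupancy])
    open_labels = open_labels[open_labels > 0]
    open_free = np.isin(labels, open_labels)
    cin = cavities & open_free
    channel = ex | mill.occupancy | cin
    g = mill.grid
    return SurgicalChannel(
        mill=mill,
        internal_cavities=BinaryMask(g, cin),
        external_space=BinaryMask(g, ex),
        channel=BinaryMask(g, channel),
    )


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------


def hemisphere_directions(axis: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Deterministic Fibonacci-spiral directions on the hemisphere about `axis`."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    ref = np.array([0.0, 1.0, 0.0]) if abs(a[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    i = np.arange(n)
    z = (i + 0.5) / n  # uniform in cos(angle) over the hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0)) + np.random.default_rng(seed).uniform(0, 2 * np.pi)
    s = np.sqrt(1.0 - z**2)
    return z[:, None] * a + s[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)


def accessibility(
    channel: SurgicalChannel,
    targets: np.ndarray,
    tool: ToolModel,
    approach_axis: np.ndarray,
    n_directions: int = 64,
    seed: int = 0,
    step_mm: float | None = None,
    eps_mm: float | None = None,
) -> float:
    """Direction-coverage accessibility mu_a in [0,1].

    For each target, the fraction of hemisphere directions (approach side)
    whose radius-r capsule from the target to the grid boundary stays inside
    the channel, judged by the channel clearance map (Euclidean distance to
    the nearest non-channel voxel); samples within ``eps_mm`` of the target
    (default one tool radius) are exempt — the target's epsilon-ball.
    """
    if n_directions < 32:
        raise ValueError("n_directions must be at least 32")
    targets = np.atleast_2d(np.asarray(targets, float))
    if len(targets) == 0:
        raise ValueError("no targets supplied")
    grid = channel.channel.grid
    sp = grid.spacing_mm
    if step_mm is None:
        step_mm = sp
    if eps_mm is None:
        eps_mm = tool.radius_mm
    clearance = ndimage.distance_transform_edt(channel.channel.occupancy, sampling=sp)

    a = -np.asarray(approach_axis, float)  # outward: from target toward the surface
    dirs = hemisphere_directions(a, n_directions, seed)

    lo = grid.origin
    hi = grid.origin + (np.asarray(grid.shape) - 1) * sp
    total = 0.0
    for t in targets:
        # distance to the grid boundary along each direction
        with np.errstate(divide="ignore"):
            s_hi = np.where(dirs > 0, (hi - t) / np.where(dirs > 0, dirs, 1), np.inf)
            s_lo = np.where(dirs < 0, (lo - t) / np.where(dirs < 0, dirs, 1), np.inf)
        s_max = np.minimum(np.min(s_hi, axis=1), np.min(s_lo, axis=1))
        n_steps = int(np.ceil(np.max(s_max) / step_mm)) + 1
        arc = np.linspace(0.0, 1.0, n_steps)
        svals = arc[None, :] * s_max[:, None]  # (n_dir, n_steps)
        pts = t + svals[..., None] * dirs[:, None, :]
        idx = grid.world_to_index(pts.reshape(-1, 3)).T
        vals = ndimage.map_coordinates(clearance, idx, order=1, mode="nearest")
        clear = vals.reshape(n_directions, n_steps) >= tool.radius_mm
        clear |= svals <= eps_mm  # epsilon-ball exemption near the target
        total += clear.all(axis=1).mean()
    return float(total / len(targets))


# ---------------------------------------------------------------------------
# Injury
# ---------------------------------------------------------------------------


def injury(
    mill: BinaryMask,
    bone: BinaryMask,
    s_structures: list[CriticalStructure],
    lambda_bone: float,
) -> float:
    """Weighted damaged-volume fraction Q_i; weights must sum to one."""
    lambdas = [s.lambda_weight for s in s_structures]
    if any(s.role != "minimize_S" for s in s_structures):
        raise ValueError("injury takes minimize_S structures only")
    if abs(lambda_bone + sum(lambdas) - 1.0) > 1e-9:
        raise ValueError("lambda_bone plus structure weights must sum to 1")
    if lambda_bone < 0 or any(l < 0 for l in lambdas):
        raise ValueError("weights must be non-negative")
    n_bone = bone.n_voxels
    if n_bone == 0:
        raise ValueError("bone mask is empty")
    q = lambda_bone * mill.n_voxels / n_bone
    for s in s_structures:
        n_s = s.mask.n_voxels
        if n_s == 0:
            raise ValueError(f"structure {s.name!r} mask is empty")
        overlap = int(np.count_nonzero(mill.occupancy & s.mask.occupancy))
        q += s.lambda_weight * overlap / n_s
    return float(q)


def default_injury_weights(n_structures: int, lambda_bone: float = 0.5) -> tuple[float, list[float]]:
    """Bone weight 0.5 by default, the remainder split equally across S structures."""
    if n_structures == 0:
        return 1.0, []
    each = (1.0 - lambda_bone) / n_structures
    return lambda_bone, [each] * n_structures


# ---------------------------------------------------------------------------
# Compactness
# ---------------------------------------------------------------------------


def _line_of_sight(points_a: np.ndarray, points_b: np.ndarray, occ: np.ndarray, grid,
                   chunk: int = 4096) -> np.ndarray:
    """Visibility of voxel-centre pairs: the half-voxel-stepped segment must
    stay inside `occ` (nearest-voxel containment).  Processed in pair chunks
    to bound memory."""
    sp = grid.spacing_mm
    shape_hi = np.asarray(grid.shape) - 1
    vis = np.empty(len(points_a), dtype=bool)
    for lo in range(0, len(points_a), chunk):
        pa = points_a[lo : lo + chunk]
        pb = points_b[lo : lo + chunk]
        diff = pb - pa
        dist = np.linalg.norm(diff, axis=1)
        n_steps = max(int(np.ceil(dist.max() / (sp / 2.0))), 1) + 1
        svals = np.linspace(0.0, 1.0, n_steps)
        pts = pa[:, None, :] + diff[:, None, :] * svals[None, :, None]
        idx = np.round(grid.world_to_index(pts.reshape(-1, 3))).astype(int)
        np.clip(idx, 0, shape_hi, out=idx)
        inside = occ[idx[:, 0], idx[:, 1], idx[:, 2]].reshape(len(pa), n_steps)
        vis[lo : lo + chunk] = inside.all(axis=1)
    return vis


def compactness(
    mask: BinaryMask,
    n_samples: int = 256,
    seed: int = 0,
    exhaustive: bool = False,
    los_mask: BinaryMask | None = None,
) -> float:
    """Global spatial compactness: sum over ordered voxel pairs of 1/d.

    Pairs whose connecting segment leaves the free space (``los_mask``,
    default the mask itself) contribute zero (d = infinity).  The full double
    sum is estimated from a seeded subsample of voxels and rescaled by
    n(n-1); ``exhaustive=True`` forces the complete sum.
    """
    occ = mask.occupancy
    los = (los_mask or mask).occupancy
    pts = mask.world_points()
    n = len(pts)
    if n == 0:
        raise ValueError("empty mask")
    if n == 1:
        return 0.0
    if exhaustive or n <= n_samples:
        sample = pts
    else:
        rng = np.random.default_rng(seed)
        sample = pts[rng.choice(n, size=n_samples, replace=False)]
    m = len(sample)
    ia, ib = np.triu_indices(m, k=1)
    pa, pb = sample[ia], sample[ib]
    vis = _line_of_sight(pa, pb, los, mask.grid)
    d = np.linalg.norm(pa - pb, axis=1)
    inv = np.where(vis, 1.0 / d, 0.0)
    # 1/d is symmetric, so the mean over unordered pairs equals the ordered-
    # pair mean; rescale by the n(n-1) ordered pairs of the full voxel set
    return float(inv.mean() * n * (n - 1))


# ---------------------------------------------------------------------------
# Boundary smoothness (spectral arc length)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothnessConfig:
    n_resample: int = 512
    n_fft: int = 4096
    cutoff_cycles: float = 20.0  # cycles per contour circuit
    # periodic Gaussian pre-smoothing of the contour, as a fraction of the
    # perimeter: suppresses raster staircase noise (wavelength ~ one pixel)
    # while leaving shape-scale undulations intact; relative to arc length so
    # the metric stays invariant under uniform scaling
    smooth_frac: float = 0.005


def union_raster(areas: list[AreaFunction]) -> np.ndarray:
    """U = 1 - prod(1 - B_t): the union of the per-target area rasters."""
    if not areas:
        raise ValueError("no areas supplied")
    out = np.zeros_like(areas[0].raster)
    for a in areas:
        out |= a.raster
    return out


def _contour_tangent_spectrum(contour_xy: np.ndarray, cfg: SmoothnessConfig):
    # resample the closed contour to uniform arc length
    pts = contour_xy
    if np.linalg.norm(pts[0] - pts[-1]) > 1e-12:
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    su = np.linspace(0.0, total, cfg.n_resample, endpoint=False)
    x = np.interp(su, s, pts[:, 0])
    y = np.interp(su, s, pts[:, 1])
    if cfg.smooth_frac > 0:
        sigma = cfg.smooth_frac * cfg.n_resample
        x = ndimage.gaussian_filter1d(x, sigma, mode="wrap")
        y = ndimage.gaussian_filter1d(y, sigma, mode="wrap")
    ds = total / cfg.n_resample
    # periodic central-difference tangent: first derivative of position wrt arc length
    xp = (np.roll(x, -1) - np.roll(x, 1)) / (2.0 * ds)
    yp = (np.roll(y, -1) - np.roll(y, 1)) / (2.0 * ds)
    # Hann window before zero-padding: the tangent signal is periodic and
    # non-zero, so padding a rect-windowed frame would smear sinc sidelobes
    # across the whole band and swamp the true harmonic structure
    sig = (xp + 1j * yp) * np.hanning(cfg.n_resample)
    spec = np.abs(np.fft.fft(sig, n=cfg.n_fft))[: cfg.n_fft // 2]
    freqs = np.arange(len(spec)) * cfg.n_resample / cfg.n_fft  # cycles per circuit
    return freqs, spec / spec.max()


def spectral_arc_length(contour_xy: np.ndarray, cfg: SmoothnessConfig = SmoothnessConfig()) -> float:
    """Spectral arc length of the contour tangent signal (<= 0; 0 is smoothest).

    mu_sa = -integral_0^wc sqrt((1/wc)^2 + (dV/dw)^2) dw with V the magnitude
    spectrum of the complex tangent x' + i y', normalised by its maximum.
    """
    if len(contour_xy) < 8:
        raise ValueError("contour shorter than 8 points")
    freqs, vhat = _contour_tangent_spectrum(np.asarray(contour_xy, float), cfg)
    wc = cfg.cutoff_cycles
    band = freqs <= wc
    f = freqs[band]
    v = vhat[band]
    dv = np.gradient(v, f)
    integrand = np.sqrt((1.0 / wc) ** 2 + dv**2)
    return float(-np.trapezoid(integrand, f))


def boundary_smoothness(
    areas: list[AreaFunction],
    cfg: SmoothnessConfig = SmoothnessConfig(),
) -> float:
    """mu_sa of the outer contour of the union of deformed area rasters."""
    u = union_raster(areas)
    pixel = areas[0].plane.pixel_mm
    contours = measure.find_contours(u.astype(float), 0.5)
    if not contours:
        raise ValueError("union raster has no contour")
    outer = max(contours, key=lambda c: len(c))
    return spectral_arc_length(outer * pixel, cfg)


# ---------------------------------------------------------------------------
# Constructability
# ---------------------------------------------------------------------------


def constructability(mu_gsc: float, mu_gsc_ref: float, mu_sa: float) -> float:
    """Q_c = -(mu_gsc / mu_gsc_ref) * exp(mu_sa); more negative is better."""
    if mu_gsc_ref <= 0:
        raise ValueError("reference compactness must be positive")
    return float(-(mu_gsc / mu_gsc_ref) * np.exp(mu_sa))
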