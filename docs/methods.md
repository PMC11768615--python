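# Methods

## Problem model

The planning domain is an isotropic voxel lattice in RAS millimetres with a
voxel-centre convention (world = origin + index·spacing; axis order R, A, S
fixed). All volumes of one plan share a single grid. The surgical channel is
C_channel = C_ex ∪ C_in ∪ C_mill: exterior space, internal cavities
connected to the milled volume or the exterior through non-bone voxels
(6-connectivity; sealed pockets are excluded), and the milled bone itself.
Critical structures carry one of two roles: *intact* structures must keep a
per-structure safe distance d_risk from the tool surface at all times;
*minimize* structures may be damaged but the damaged fraction is penalised
with weight λ. The tool is a cylinder of radius r; r is also used as the
contour resampling interval, the closing-kernel half-width and the
entry-thinning scale, so a single physical dimension drives all of the
overlap reasoning.

Default safe distances are 0.5 mm for small ducts/ossicle-class and
vessel-class structures, 1.5 mm for dural-sheet (sinus) structures and
2.5 mm for nerve-class structures; all are overridable per structure.

## Distance queries

Every safety predicate reduces to "minimum distance from a segment to a
structure". Per structure a signed distance field is precomputed from its
mask with Euclidean distance transforms: outside voxels carry the distance
to the nearest occupied voxel centre, inside voxels the negative distance to
the nearest background voxel centre, so penetration is detectable by sign.
Segment queries sample the field at ≤ half a voxel spacing and interpolate
trilinearly; a nearest-voxel lookup mode exists for comparison but the
interpolated mode is the default (at 0.25–1 mm lattices it is strictly more
accurate at negligible cost). Queries outside the grid raise — planning
grids are generated with enough background padding that trajectories never
leave bounds. Fidelity bounds asserted in the suite: agreement with the
brute-force all-pairs oracle within half a voxel diagonal, and agreement
with closed-form capsule/box distances within half a voxel diagonal plus the
sampling step.

## Maximum milling area

Entry candidates are outer bone-surface voxels whose outward normal (SDF
gradient) faces the approach and whose lateral offset from the approach axis
through the target centroid is at most a configurable window (14 mm on the
default phantom). A trajectory (k, t) is feasible iff every intact structure
keeps distance > r + d_risk from the segment. Feasible cylinders — open
finite cylinders, caps excluded, voxel-centre membership — are accumulated
per target in a deterministic near-to-far sweep (ordered by distance from
the entry nearest the approach axis, lexicographic tie-breaks). The sweep
stops early once the normalised volume gain
G_t(k) = ΔV / (|kt|·πr²) stays below 5×10⁻⁴ for 25 consecutive *feasible*
entries; infeasible entries do not advance the counter, so a blocked arc
cannot truncate the sweep before a distant feasible region is reached. The
suite checks that early termination changes the union volume by < 2%
against the exhaustive sweep.

## Effective-target extraction

The dense target surface is reduced in four stages: (T1) keep surface
points whose outward normal faces "enough" entries — the facing count r_t
must strictly exceed both its mean and 5% of |K|; (T2) keep points with at
least one feasible trajectory, testing entries thinned to a 2r world grid
(lowest-index representative per cell, first success wins); (T3) take the
ordered boundary contour of the reachable patch (largest 26-connected
component if fragmented), ordered clockwise by polar angle of the
control-plane projection about the projected centroid — clockwise is
defined looking along the approach direction, one convention enforced and
tested; (T4) greedy arc-length downsampling at interval r so adjacent
access trajectories overlap. Surface normals come from the gradient of the
target SDF after a one-voxel Gaussian smooth: raw distance-transform
gradients are lattice-quantised and misestimate sphere normals by tens of
degrees, while the smoothed field recovers them to a few degrees. On the
default phantom the cascade retains a few tens of rim points
(8 spline knots each ⇒ on the order of 10²–2·10² parameters).

## Parameterization and reconstruction

All per-target area functions share one control plane placed just beyond
the outermost entry, normal along the approach-side R axis, origin at the
projected target centroid, pixel pitch equal to the planning voxel spacing.
Entries project along the ray t→k; cells shared by several entries remember
the entry nearest the plane. The raster is closed with a square kernel of
half-width r — a round structuring element provably cannot bridge two
isolated projected samples one pixel apart (its erosion always fails at the
midpoint), while the square kernel gives the intended gap-bridging; cells
added by closing inherit the entry of their nearest projected cell so every
raster cell stays backed by a feasibility-checked trajectory.

The control function σ(θ) is a periodic cubic spline through N = 8 uniform
knots, clipped to [10⁻³, 1]; the lower clip keeps the open interval (0,1]
while avoiding division blow-up in the ρ/σ lookup. Deformation keeps a cell
(ρ,θ) iff the cell at (ρ/σ(θ), θ) — looked up nearest-cell — is occupied,
ANDed with the cell's own occupancy (subset restriction), about the mass
centre of the *undeformed* raster; the centre is frozen so the
parameter-to-shape map is stationary across optimisation iterations.
Reconstruction unions the cylinders of the surviving cells' entries; a
per-(target, entry) voxel-index cache makes a reconstruction a few
milliseconds inside the optimisation loop. Only bone voxels of the swept
union count as milled volume — the remainder of the sweep is cavity or
exterior and becomes part of the channel.

## Metrics

*Accessibility.* μ_a averages over targets the fraction of
deterministically sampled hemisphere directions (Fibonacci spiral on the
approach side, seeded) whose radius-r capsule from the target to the grid
boundary stays inside the channel, judged against the channel clearance
map (EDT of the channel); samples within an ε-ball (default r) of the
target are exempt. This operationalises "difficulty of accessing the
target through the channel" as direction coverage; it is isolated behind
one function so an alternative definition can be swapped in. It is
monotone in the channel by construction.

*Injury.* Q_i = λ_bone·V(C_mill)/V(C_bone) + Σ_j λ_j·V(C_mill∩C_sj)/V(C_sj)
with λ_bone + Σλ_j = 1 validated to 10⁻⁹. Default weights: λ_bone = 0.5,
remainder split equally across minimize-structures.

*Compactness.* μ_gsc sums 1/d over ordered voxel pairs of the milled
volume, zero for pairs whose connecting segment (half-voxel steps,
nearest-voxel containment) leaves the free space. The full double sum is
estimated from a seeded subsample (mean over sampled pairs × n(n−1));
an exhaustive mode serves as the oracle in tests (within 5% on
sub-3000-voxel shapes). The metric is computed on the milled volume by
default (switchable to the full channel).

*Smoothness.* μ_sa is the spectral arc length of the tangent signal
x′ + iy′ of the outer contour of the union of deformed area rasters:
resampled to 512 uniform arc-length points, FFT zero-padded to 4096,
magnitude spectrum normalised by its maximum, integrated to a cutoff of 20
cycles per circuit. Two signal-processing details matter on rasters and are
exposed in `SmoothnessConfig`: the contour is pre-smoothed with a periodic
Gaussian of σ = 0.5% of the perimeter (scale-relative, so uniform scaling
invariance holds to 10⁻³) to suppress marching-squares staircase noise, and
the tangent signal is Hann-windowed before the zero-padded FFT — a
periodic, non-zero signal padded behind a rect window otherwise smears sinc
sidelobes across the whole band and makes a rasterized circle score worse
than a star, inverting the metric's intended ordering.

*Constructability.* Q_c = −(μ_gsc/μ_gsc(C_mill⁽⁰⁾))·e^{μ_sa}; the
reference compactness is computed once on the bone-restricted maximum
milling area with the same sampling seed, so the all-ones plan anchors at
Q_c = −e^{μ_sa}.

## Optimisation

The decision vector is the flattened knot matrix, box-bounded to
(10⁻³, 1]. NSGA-III is implemented in-package: Das–Dennis reference
directions on the 3-simplex, fast non-dominated sorting, hyperplane
normalisation with achievement-scalarised extreme points (front-wise
max fallback on degenerate intercepts), perpendicular-distance association
and niche-preserving selection; SBX crossover (η = 15, p = 0.9) and
polynomial mutation (η = 20, p = 1/n) with bound repair. All stochastic
steps draw from one seeded generator, so runs are bit-reproducible. The
all-ones individual (the maximum milling area) seeds generation 0.
Vanished plans (all areas deformed to empty, or no bone milled) are
penalised with a 10⁶ objective triple rather than raising — the
evolutionary loop needs a total function. Defaults are population 92
(12 Das–Dennis partitions → 91 directions) and 100 generations; the test
and acceptance profile uses population 40 / 30 generations / 7 partitions,
which converges on the phantom scene in about two minutes on one core.
Selection takes the compromise-programming pick (L2 to the ideal point on
min–max-normalised objectives) and the equal-weight pseudo-weight pick,
then keeps whichever reconstructs to the larger μ_gsc; provenance is
recorded.

## The phantom and what it does (not) show

The generator rasterises closed-form shapes — capsules, axis-aligned
boxes/sheets, ellipsoids — onto one grid and echoes every parameter in a
manifest so tests can build analytic oracles. The default scene (64 mm
cube, 1 mm spacing): a bone slab with outer face at R = 44 mm and a
sinusoidally modulated inner face (thickness 6–10 mm, phases drawn from the
seed), an ellipsoidal target at depth, a nerve-class tube (d_risk 2.5 mm)
and vessel tube (0.5 mm) and a dural sheet (1.5 mm) flanking a 6 mm
corridor whose clearance over r + d_risk is validated analytically at build
time (so at least one feasible trajectory always exists), and a scala-like
minimize-S duct embedded in the slab placed so the maximum milling area
clips 5–20% of it — giving the optimiser a real injury gradient. Identical
seeds produce bit-identical volumes.

What passing on the phantom does *not* show: robustness to segmentation
error, anisotropic or noisy CT lattices, non-convex or multi-lesion
targets, or anatomy whose feasible corridor is not simply connected. The
phantom's constraint topology matches the clinical scene; its geometry is
far cleaner.

## Numerical choices and degenerate inputs

- Planning resolution: the pipeline supports resampling to 0.25 mm; tests
  and the acceptance profile run at 1 mm (with individual operations
  verified at 0.25–0.5 mm) to keep the full stack at desk-scale runtimes.
- Ties: entry ordering breaks ties lexicographically by world coordinate;
  shared projection cells keep the entry nearest the plane; the strict
  mean-threshold in T1 excludes ties.
- Degenerate inputs raise with stage-specific messages: empty/full masks
  for SDFs, coincident segment endpoints, <3 or collinear landmarks,
  oblique NIfTI affines (naming the offending axis), targets with no
  feasible entry (dropped with a warning; all-empty aborts), contours
  shorter than 8 points, vanished plans outside the optimiser.
- Targets dropped for infeasibility are reported on the plan report, not
  silently discarded.

## Known limitations

- The tool is a cylinder; burrs with shaped tips or curved access paths are
  out of scope.
- The accessibility functional is a documented stand-in (direction
  coverage with capsule clearance) for an external construct the problem
  statement references but does not define.
- The deformation is star-shaped about the area's mass centre; strongly
  non-convex feasible areas would need multiple control planes.
- Landmark alignment is rigid (SVD/Kabsch); deformable registration and
  atlas construction are intentionally outside the package — it consumes
  segmentation masks directly.
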