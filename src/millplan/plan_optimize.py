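"""Three-objective milling-plan optimisation and Pareto-front selection.

The decision vector is the flattened sigma matrix (one row of N spline
knots per retained target, each value in (eps, 1]).  Objectives, all
minimised, are (Q_c, Q_a, Q_i): constructability, negated accessibility and
injury of the reconstructed milling volume.  Spatial feasibility is
structural — any parameter vector reconstructs a union of feasibility-
checked cylinders — so the only constraints are the box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import nsga3
from .area_param import SIGMA_FLOOR, MillingReconstructor, ParameterSet
from .channel_eval import (
    SmoothnessConfig,
    accessibility,
    boundary_smoothness,
    build_channel,
    compactness,
    constructability,
    injury,
)
from .max_milling import ToolModel
from .volume_core import BinaryMask, CriticalStructure

PENALTY = 1e6  # objective triple for vanished plans; keeps the loop total


@dataclass(frozen=True)
class EvalConfig:
    """Deterministic settings shared by every objective evaluation."""

    approach_axis: tuple[float, float, float] = (-1.0, 0.0, 0.0)
    n_directions: int = 32
    accessibility_seed: int = 0
    compactness_samples: int = 64
    compactness_seed: int = 0
    lambda_bone: float = 0.5
    smoothness: SmoothnessConfig = field(default_factory=SmoothnessConfig)


@dataclass(frozen=True)
class OptimizationConfig:
    population_size: int = 92
    n_generations: int = 100
    reference_partitions: int = 12
    seed: int = 0
    eta_crossover: float = 15.0
    p_crossover: float = 0.9
    eta_mutation: float = 20.0
    p_mutation: float | None = None
    sigma_floor: float = SIGMA_FLOOR


@dataclass
class ParetoResult:
    X: np.ndarray  # (n, dim) parameter vectors, mutually non-dominated
    F: np.ndarray  # (n, 3) objective triples (Q_c, Q_a, Q_i)
    n_targets: int
    n_knots: int
    selected: int | None = None
    selection_provenance: str = ""

    def parameter_set(self, i: int) -> ParameterSet:
        return ParameterSet(self.X[i].reshape(self.n_targets, self.n_knots))


@dataclass
class PlanningProblem:
    objective: Callable[[np.ndarray], np.ndarray]
    reconstructor: MillingReconstructor
    n_targets: int
    n_knots: int
    mu_gsc_ref: float
    mu_gsc_of: Callable[[np.ndarray], float]
    mill_of: Callable[[np.ndarray], BinaryMask]


def make_problem(
    reconstructor: MillingReconstructor,
    max_area_mask: BinaryMask,
    bone: BinaryMask,
    head_region: BinaryMask,
    targets: np.ndarray,
    s_structures: list[CriticalStructure],
    tool: ToolModel,
    n_knots: int,
    eval_config: EvalConfig = EvalConfig(),
) -> PlanningProblem:
    """Build the pure objective function P -> (Q_c, Q_a, Q_i).

    The reconstructed cylinder union is restricted to bone (only bone is
    milled; the rest of the sweep is cavity or exterior and becomes channel).
    ``max_area_mask`` should be the bone-restricted maximum milling area,
    on which the compactness reference mu_gsc(C_mill^(0)) is computed once.
    Evaluation seeds are fixed in ``eval_config`` so the same parameters
    always give bitwise-identical objectives.  A parameter vector whose
    deformed areas all vanish is penalised instead of raising, keeping the
    evolutionary loop alive.
    """
    ec = eval_config
    lam_s = [s.lambda_weight for s in s_structures]
    if s_structures and abs(ec.lambda_bone + sum(lam_s) - 1.0) > 1e-9:
        raise ValueError("injury weights do not sum to 1")

    mu_gsc_ref = compactness(
        max_area_mask, n_samples=ec.compactness_samples, seed=ec.compactness_seed
    )

    def mill_of(params: np.ndarray) -> BinaryMask:
        swept = reconstructor.reconstruct(params)
        return BinaryMask(swept.grid, swept.occupancy & bone.occupancy)

    def mu_gsc_of(x: np.ndarray) -> float:
        mill = mill_of(x.reshape(reconstructor.n_targets, n_knots))
        return compactness(mill, n_samples=ec.compactness_samples, seed=ec.compactness_seed)

    def objective(x: np.ndarray) -> np.ndarray:
        params = x.reshape(reconstructor.n_targets, n_knots)
        try:
            mill = mill_of(params)
        except ValueError:
            return np.array([PENALTY, PENALTY, PENALTY])
        if mill.n_voxels == 0:
            return np.array([PENALTY, PENALTY, PENALTY])
        channel = build_channel(mill, bone, head_region)
        mu_a = accessibility(
            channel,
            targets,
            tool,
            approach_axis=ec.approach_axis,
            n_directions=ec.n_directions,
            seed=ec.accessibility_seed,
        )
        q_i = injury(mill, bone, s_structures, ec.lambda_bone) if s_structures else injury(
            mill, bone, [], 1.0
        )
        mu_gsc = compactness(
            mill, n_samples=ec.compactness_samples, seed=ec.compactness_seed
        )
        mu_sa = boundary_smoothness(reconstructor.deformed_areas(params), ec.smoothness)
        q_c = constructability(mu_gsc, mu_gsc_ref, mu_sa)
        return np.array([q_c, -mu_a, q_i])

    return PlanningProblem(
        objective=objective,
        reconstructor=reconstructor,
        n_targets=reconstructor.n_targets,
        n_knots=n_knots,
        mu_gsc_ref=mu_gsc_ref,
        mu_gsc_of=mu_gsc_of,
        mill_of=lambda x: mill_of(np.atleast_2d(x).reshape(reconstructor.n_targets, n_knots)),
    )


def run_nsga3(problem: PlanningProblem, config: OptimizationConfig = OptimizationConfig()) -> ParetoResult:
    """NSGA-III over the box (eps,1]^(N_T*N); the all-ones plan seeds generation 0."""
    dim = problem.n_targets * problem.n_knots
    ref_dirs = nsga3.das_dennis(config.reference_partitions, 3)
    pop = max(config.population_size, len(ref_dirs))
    res = nsga3.minimize_nsga3(
        problem.objective,
        n_var=dim,
        lower=np.full(dim, config.sigma_floor),
        upper=np.ones(dim),
        pop_size=pop,
        n_generations=config.n_generations,
        ref_dirs=ref_dirs,
        seed=config.seed,
        initial=np.ones((1, dim)),
        eta_crossover=config.eta_crossover,
        p_crossover=config.p_crossover,
        eta_mutation=config.eta_mutation,
        p_mutation=config.p_mutation,
    )
    return ParetoResult(res.X, res.F, problem.n_targets, problem.n_knots)


def compromise_pick(F: np.ndarray) -> int:
    """Solution nearest (L2) to the ideal point on min-max-normalised objectives."""
    lo = F.min(axis=0)
    span = F.max(axis=0) - lo
    span = np.where(span < 1e-12, 1.0, span)
    Fn = (F - lo) / span
    return int(np.argmin(np.linalg.norm(Fn, axis=1)))


def pseudo_weight_pick(F: np.ndarray, weights: np.ndarray | None = None) -> int:
    """Pseudo-weight selection: normalised marginal improvement closest to
    the requested weight vector (equal thirds by default)."""
    if weights is None:
        weights = np.full(F.shape[1], 1.0 / F.shape[1])
    lo = F.min(axis=0)
    hi = F.max(axis=0)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    w = (hi - F) / span
    w_sum = w.sum(axis=1, keepdims=True)
    w_sum = np.where(w_sum < 1e-12, 1.0, w_sum)
    w = w / w_sum
    return int(np.argmin(np.linalg.norm(w - weights, axis=1)))


def select_solution(front: ParetoResult, mu_gsc_of: Callable[[np.ndarray], float]) -> ParetoResult:
    """Pick the final plan from the Pareto front.

    Candidate 1 is the compromise-programming pick, candidate 2 the equal-
    weight pseudo-weight pick; of the two, the plan whose reconstructed
    volume has the larger global spatial compactness wins.  Provenance is
    recorded on the returned result.
    """
    if len(front.F) == 0:
        raise ValueError("empty Pareto front")
    if len(front.F) == 1:
        front.selected = 0
        front.selection_provenance = "degenerate front"
        return front
    c1 = compromise_pick(front.F)
    c2 = pseudo_weight_pick(front.F)
    if c1 == c2:
        front.selected = c1
        front.selection_provenance = "agreement"
        return front
    g1 = mu_gsc_of(front.X[c1])
    g2 = mu_gsc_of(front.X[c2])
    if g1 >= g2:
        front.selected = c1
        front.selection_provenance = "compromise programming (larger mu_gsc)"
    else:
        front.selected = c2
        front.selection_provenance = "pseudo-weight (larger mu_gsc)"
    return front
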