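"""End-to-end planning pipeline: phantom/volumes in, selected milling plan out.

Stage order: ingestion -> signed distance fields -> entry candidates ->
effective-target extraction -> maximum milling area -> control-plane
parameterization -> NSGA-III optimisation -> Pareto selection -> final
evaluation.  Every stage's artifacts are kept on the report so stages can be
inspected (and tested) in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .area_param import MillingReconstructor, ParameterSet, make_control_plane, project_entries
from .channel_eval import (
    EvaluationResult,
    accessibility,
    boundary_smoothness,
    build_channel,
    compactness,
    constructability,
    injury,
)
from .max_milling import (
    MaxMillingArea,
    TerminationConfig,
    ToolModel,
    feasibility_matrix,
    find_entry_candidates,
    generate_max_area,
)
from .phantom import Phantom, PhantomSpec, generate_phantom
from .plan_optimize import (
    EvalConfig,
    OptimizationConfig,
    ParetoResult,
    make_problem,
    run_nsga3,
    select_solution,
)
from .target_extraction import extract_targets
from .volume_core import BinaryMask, compute_sdf, write_nifti


@dataclass
class RunConfig:
    """Validated configuration of one planning run."""

    tool_radius_mm: float = 1.5
    spacing_mm: float = 1.0
    entry_max_offset_mm: float = 14.0
    n_control_points: int = 8
    termination_threshold: float = 5e-4
    termination_window: int = 25
    population_size: int = 40
    n_generations: int = 30
    reference_partitions: int = 7
    seed: int = 0
    n_directions: int = 32
    compactness_samples: int = 64
    lambda_bone: float = 0.5

    def __post_init__(self) -> None:
        positives = {
            "tool_radius_mm": self.tool_radius_mm,
            "spacing_mm": self.spacing_mm,
            "entry_max_offset_mm": self.entry_max_offset_mm,
            "n_control_points": self.n_control_points,
            "termination_threshold": self.termination_threshold,
            "termination_window": self.termination_window,
            "population_size": self.population_size,
            "n_generations": self.n_generations,
        }
        for name, val in positives.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive (got {val})")
        if not (0.0 <= self.lambda_bone <= 1.0):
            raise ValueError("lambda_bone must lie in [0,1]")
        if self.n_directions < 32:
            raise ValueError("n_directions must be at least 32")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PlanReport:
    config: RunConfig
    n_entries: int
    n_targets: int
    n_parameters: int
    max_area: MaxMillingArea
    front: ParetoResult
    selected_mill: BinaryMask
    metrics_initial: dict
    metrics_selected: dict
    timings_s: dict
    dropped_targets: list[int]

    def summary(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_entries": self.n_entries,
            "n_targets": self.n_targets,
            "n_parameters": self.n_parameters,
            "front_size": len(self.front.F),
            "selected_index": self.front.selected,
            "selection_provenance": self.front.selection_provenance,
            "metrics_initial": self.metrics_initial,
            "metrics_selected": self.metrics_selected,
            "timings_s": self.timings_s,
        }


def evaluate_plan(
    mill: BinaryMask,
    bone: BinaryMask,
    head: BinaryMask,
    targets: np.ndarray,
    s_structures,
    tool: ToolModel,
    areas,
    mu_gsc_ref: float,
    ec: EvalConfig,
) -> EvaluationResult:
    channel = build_channel(mill, bone, head)
    mu_a = accessibility(
        channel, targets, tool, ec.approach_axis, ec.n_directions, ec.accessibility_seed
    )
    q_i = injury(mill, bone, s_structures, ec.lambda_bone if s_structures else 1.0)
    mu_gsc = compactness(mill, ec.compactness_samples, ec.compactness_seed)
    mu_sa = boundary_smoothness(areas, ec.smoothness)
    q_c = constructability(mu_gsc, mu_gsc_ref, mu_sa)
    return EvaluationResult(mu_a, -mu_a, q_i, mu_gsc, mu_gsc_ref, mu_sa, q_c)


def run_pipeline(config: RunConfig, phantom: Phantom | None = None) -> PlanReport:
    """Execute the full planning pipeline on a phantom scene.

    When no phantom is supplied, the default scene is generated at the
    configured spacing with the configured seed.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    if phantom is None:
        phantom = generate_phantom(
            PhantomSpec(seed=config.seed, spacing_mm=config.spacing_mm,
                        tool_radius_mm=config.tool_radius_mm)
        )
    grid = phantom.grid
    tool = ToolModel(config.tool_radius_mm)
    approach = phantom.spec.approach_axis
    intact = phantom.intact_structures
    minimize = phantom.minimize_structures
    timings["ingest"] = time.perf_counter() - t0

    # entry candidates on the outer skull surface
    t0 = time.perf_counter()
    centroid = phantom.target.world_points().mean(axis=0)
    entries = find_entry_candidates(phantom.bone, centroid, approach, config.entry_max_offset_mm)
    timings["entries"] = time.perf_counter() - t0

    # shared control plane and effective-target cascade
    t0 = time.perf_counter()
    plane = make_control_plane(centroid, entries, approach, grid.spacing_mm)
    stages = extract_targets(phantom.target, entries, intact, tool, plane)
    targets = stages["T4"].points_mm
    timings["targets"] = time.perf_counter() - t0

    # maximum milling area
    t0 = time.perf_counter()
    feas = feasibility_matrix(entries, targets, intact, tool)
    max_area = generate_max_area(
        targets,
        entries,
        intact,
        tool,
        grid,
        TerminationConfig(True, config.termination_threshold, config.termination_window),
        approach,
        feasibility=feas,
    )
    timings["max_area"] = time.perf_counter() - t0

    # parameterization
    t0 = time.perf_counter()
    kept = sorted(max_area.per_target_entries)
    areas = [
        project_entries(targets[ti], max_area.per_target_entries[ti], plane, tool) for ti in kept
    ]
    recon = MillingReconstructor(areas, tool, grid)
    n_params = len(areas) * config.n_control_points
    timings["parameterize"] = time.perf_counter() - t0

    # optimisation
    t0 = time.perf_counter()
    ec = EvalConfig(
        approach_axis=tuple(approach),
        n_directions=config.n_directions,
        accessibility_seed=config.seed,
        compactness_samples=config.compactness_samples,
        compactness_seed=config.seed,
        lambda_bone=config.lambda_bone if minimize else 1.0,
    )
    kept_targets = targets[kept]
    max_area_bone = BinaryMask(grid, max_area.union_mask.occupancy & phantom.bone.occupancy)
    problem = make_problem(
        recon, max_area_bone, phantom.bone, phantom.head_region,
        kept_targets, minimize, tool, config.n_control_points, ec,
    )
    oc = OptimizationConfig(
        population_size=config.population_size,
        n_generations=config.n_generations,
        reference_partitions=config.reference_partitions,
        seed=config.seed,
    )
    front = run_nsga3(problem, oc)
    front = select_solution(front, problem.mu_gsc_of)
    timings["optimize"] = time.perf_counter() - t0

    # final evaluation of initial (all-ones) and selected plans
    t0 = time.perf_counter()
    ones = ParameterSet.ones(len(areas), config.n_control_points)
    mill_initial = problem.mill_of(ones.values)
    initial_metrics = evaluate_plan(
        mill_initial, phantom.bone, phantom.head_region, kept_targets, minimize, tool,
        recon.deformed_areas(ones), problem.mu_gsc_ref, ec,
    )
    sel_params = front.parameter_set(front.selected)
    mill_sel = problem.mill_of(sel_params.values)
    sel_metrics = evaluate_plan(
        mill_sel, phantom.bone, phantom.head_region, kept_targets, minimize, tool,
        recon.deformed_areas(sel_params), problem.mu_gsc_ref, ec,
    )
    timings["evaluate"] = time.perf_counter() - t0

    return PlanReport(
        config=config,
        n_entries=len(entries),
        n_targets=len(areas),
        n_parameters=n_params,
        max_area=max_area,
        front=front,
        selected_mill=mill_sel,
        metrics_initial=initial_metrics.as_dict(),
        metrics_selected=sel_metrics.as_dict(),
        timings_s={k: round(v, 3) for k, v in timings.items()},
        dropped_targets=max_area.dropped_targets,
    )


def write_report(report: PlanReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.summary(), indent=2))
    write_nifti(report.selected_mill, out / "selected_mill.nii.gz")
    write_nifti(report.max_area.union_mask, out / "max_area.nii.gz")
    np.savetxt(
        out / "front.csv",
        np.hstack([report.front.F, report.front.X]),
        delimiter=",",
        header="Q_c,Q_a,Q_i,params...",
        comments="",
    )
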