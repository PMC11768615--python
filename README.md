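# millplan

Automated volumetric milling-area planning for mastoidectomy in lateral
skull-base (acoustic neuroma) surgery.

In the translabyrinthine approach the surgeon mills away part of the
temporal bone to open a corridor to a deep tumour. The removed volume —
the *milling area* C_mill — must expose the surgical target, stay clear of
structures that must remain intact (sinus dura, facial nerve, vessels;
each with a safe distance d_risk), limit damage to structures that may be
touched but are penalised (e.g. the scala vestibuli, weight λ), and remain
constructable with a cylindrical burr of radius r. `millplan` turns this
volumetric planning problem into a low-dimensional continuous optimisation
and solves it with a many-objective evolutionary algorithm.

## Method in brief

1. **Maximum milling area.** Candidate entry points K on the outer skull
   surface and effective target points T on the tumour surface are paired;
   a pair (k, t) is feasible when the tool axis keeps margin
   d(p, l(k,t)) > r + d_risk_i from every intact structure i (signed
   distance fields answer these queries). The union of all feasible tool
   cylinders C(k,t) is the maximum permissible milling area
   C_mill⁽⁰⁾ = ⋃_t ⋃_k I(k,t)·C(k,t).
2. **Parameterization.** For each retained target t, its feasible entries
   are projected along t→k onto a control plane parallel to the A–S plane,
   giving a 2-D area function B_t. A periodic spline control function
   σ_t(θ) ∈ (0,1] with N = 8 knots shrinks B_t radially about its mass
   centre, with a subset restriction h′(B_t)(ρ,θ) = B_t(ρ/σ(θ),θ)·B_t(ρ,θ)
   so deformed plans never leave the feasible region. A plan is then just
   the knot matrix P ∈ (0,1]^{N_T × 8}.
3. **Objectives.** Each candidate volume is scored by accessibility
   Q_a = −μ_a (direction coverage of each target through the channel),
   injury Q_i (weighted damaged-volume fractions of bone and penalised
   structures, weights summing to 1) and constructability
   Q_c = −(μ_gsc/μ_gsc(C_mill⁽⁰⁾))·e^{μ_sa}, combining obstacle-aware
   global spatial compactness μ_gsc with the spectral-arc-length boundary
   smoothness μ_sa of the union contour on the control plane.
4. **Optimisation.** NSGA-III minimises (Q_c, Q_a, Q_i) over the box
   (ε,1]^{8·N_T}; the final plan is chosen from the Pareto front by
   compromise programming vs. the pseudo-weight rule, breaking the tie
   toward the larger μ_gsc.

Because clinical CT volumes and their expert segmentations cannot ship
with the package, a deterministic phantom generator
(`millplan.phantom`) builds a temporal-bone-like scene from closed-form
shapes — a bone slab of varying thickness, an ellipsoidal deep target,
nerve/vessel tubes and a dural sheet flanking the corridor, and a
scala-like duct grazing the milling fan — so every stage has an analytic
oracle.

## Worked example

```bash
millplan plan --seed 1 --out scratch/run1
```

runs the full pipeline on the default phantom (64 mm cube at 1 mm spacing,
r = 1.5 mm, d_risk = 2.5/1.5/0.5 mm for the nerve/sheet/vessel) and prints
a report like:

```
"n_targets": 18,            # effective target points after the T0->T4 cascade
"n_parameters": 144,        # 8 spline knots per retained target
"metrics_initial":  { "mu_a": 0.524, "Q_i": 0.127, "mu_sa": -2.19, ... }
"metrics_selected": { "mu_a": 0.523, "Q_i": 0.067, "mu_sa": -2.13, ... }
```

Read: the optimiser kept target accessibility essentially unchanged
(μ_a 0.524 → 0.523) while cutting the weighted injury Q_i roughly in half
(0.127 → 0.067) — the milling fan retreats from the penalised duct — and
slightly smoothing the channel boundary (μ_sa −2.19 → −2.13; closer to 0
is smoother). The selected mask, the full Pareto front and the maximum
milling area are written as NIfTI/CSV artifacts next to the report.

The same stages are available as library calls (`generate_phantom`,
`find_entry_candidates`, `extract_targets`, `generate_max_area`,
`project_entries`, `MillingReconstructor`, `make_problem`, `run_nsga3`,
`select_solution`); see the test suite for worked fixtures.

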