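"""Reference-direction-based many-objective evolutionary optimizer (NSGA-III).

Self-contained implementation of the standard algorithm: Das-Dennis
structured reference directions on the objective simplex, fast
non-dominated sorting, hyperplane normalisation with achievement-
scalarising extreme points, perpendicular-distance association, and niche-
preserving selection on the splitting front.  Variation uses simulated
binary crossover and polynomial mutation with box-bound repair.

Everything is driven by a single ``numpy.random.Generator`` so runs are
bit-for-bit reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


def das_dennis(n_partitions: int, n_obj: int = 3) -> np.ndarray:
    """Structured reference points on the unit simplex."""

    def recurse(left: int, depth: int) -> list[list[int]]:
        if depth == n_obj - 1:
            return [[left]]
        out = []
        for i in range(left + 1):
            for rest in recurse(left - i, depth + 1):
                out.append([i] + rest)
        return out

    pts = np.asarray(recurse(n_partitions, 0), dtype=float)
    return pts / n_partitions


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Indices of successive non-dominated fronts (minimisation)."""
    n = len(F)
    # a dominates b iff <= everywhere and < somewhere
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dom = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = np.where(remaining & (n_dom == 0))[0]
        if len(current) == 0:  # numerical duplicates; dump the rest
            current = np.where(remaining)[0]
        fronts.append(current)
        remaining[current] = False
        n_dom = n_dom - dom[current].sum(axis=0)
    return fronts


def _normalize(F: np.ndarray, front0: np.ndarray) -> np.ndarray:
    """Hyperplane normalisation: translate by the ideal point, divide by
    intercepts from achievement-scalarised extreme points."""
    ideal = F.min(axis=0)
    Ft = F - ideal
    n_obj = F.shape[1]
    weights = np.eye(n_obj) + 1e-6
    extremes = np.array(
        [front0[np.argmin(np.max(Ft[front0] / w, axis=1))] for w in weights]
    )
    intercepts = None
    try:
        mat = Ft[extremes]
        b = np.ones(n_obj)
        plane = np.linalg.solve(mat, b)
        intercepts = 1.0 / plane
        if np.any(intercepts < 1e-12) or not np.all(np.isfinite(intercepts)):
            intercepts = None
    except np.linalg.LinAlgError:
        intercepts = None
    if intercepts is None:
        intercepts = Ft[front0].max(axis=0)
    intercepts = np.where(intercepts < 1e-12, 1.0, intercepts)
    return Ft / intercepts


def _associate(Fn: np.ndarray, ref_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction (perpendicular distance) per solution."""
    norms = np.linalg.norm(ref_dirs, axis=1)
    unit = ref_dirs / norms[:, None]
    proj = Fn @ unit.T  # (n, R)
    perp2 = np.maximum(np.sum(Fn**2, axis=1)[:, None] - proj**2, 0.0)
    dist = np.sqrt(perp2)
    nearest = np.argmin(dist, axis=1)
    return nearest, dist[np.arange(len(Fn)), nearest]


def nsga3_survival(F: np.ndarray, ref_dirs: np.ndarray, n_survive: int, rng: np.random.Generator) -> np.ndarray:
    """Select ``n_survive`` indices from the merged population (standard niching)."""
    fronts = fast_nondominated_sort(F)
    chosen: list[int] = []
    k = 0
    while k < len(fronts) and len(chosen) + len(fronts[k]) <= n_survive:
        chosen.extend(fronts[k].tolist())
        k += 1
    if len(chosen) == n_survive or k >= len(fronts):
        return np.asarray(chosen[:n_survive], dtype=int)

    split = fronts[k]
    considered = np.asarray(chosen + split.tolist(), dtype=int)
    Fn = _normalize(F[considered], np.arange(len(chosen) + len(split)))
    nearest, perp = _associate(Fn, ref_dirs)
    n_sel = len(chosen)
    niche_count = np.bincount(nearest[:n_sel], minlength=len(ref_dirs))
    cand_ref = nearest[n_sel:]
    cand_perp = perp[n_sel:]
    available = np.ones(len(split), dtype=bool)
    while len(chosen) < n_survive:
        refs_with_cand = np.unique(cand_ref[available])
        j_min = refs_with_cand[np.argmin(niche_count[refs_with_cand])]
        ties = refs_with_cand[niche_count[refs_with_cand] == niche_count[j_min]]
        j = ties[rng.integers(len(ties))]
        cands = np.where(available & (cand_ref == j))[0]
        if niche_count[j] == 0:
            pick = cands[np.argmin(cand_perp[cands])]
        else:
            pick = cands[rng.integers(len(cands))]
        chosen.append(int(split[pick]))
        available[pick] = False
        niche_count[j] += 1
    return np.asarray(chosen, dtype=int)


def sbx_crossover(
    parents: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    eta: float,
    prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs."""
    X = parents.copy()
    n, dim = X.shape
    for i in range(0, n - 1, 2):
        if rng.random() > prob:
            continue
        p1, p2 = X[i].copy(), X[i + 1].copy()
        for d in range(dim):
            if rng.random() > 0.5 or abs(p1[d] - p2[d]) < 1e-14:
                continue
            x1, x2 = min(p1[d], p2[d]), max(p1[d], p2[d])
            u = rng.random()
            beta = (2 * u) ** (1.0 / (eta + 1)) if u <= 0.5 else (1.0 / (2 * (1 - u))) ** (
                1.0 / (eta + 1)
            )
            c1 = 0.5 * ((x1 + x2) - beta * (x2 - x1))
            c2 = 0.5 * ((x1 + x2) + beta * (x2 - x1))
            if rng.random() < 0.5:
                c1, c2 = c2, c1
            X[i, d] = np.clip(c1, lower[d], upper[d])
            X[i + 1, d] = np.clip(c2, lower[d], upper[d])
    return X


def polynomial_mutation(
    X: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    eta: float,
    prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polynomial mutation with per-gene probability and bound repair."""
    Y = X.copy()
    span = upper - lower
    mutate = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    delta1 = (Y - lower) / span
    delta2 = (upper - Y) / span
    mut_pow = 1.0 / (eta + 1.0)
    low_side = u < 0.5
    val_low = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - delta1) ** (eta + 1.0)
    d_low = val_low**mut_pow - 1.0
    val_high = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - delta2) ** (eta + 1.0)
    d_high = 1.0 - val_high**mut_pow
    delta = np.where(low_side, d_low, d_high)
    Y = np.where(mutate, Y + delta * span, Y)
    return np.clip(Y, lower, upper)


@dataclass
class NSGA3Result:
    X: np.ndarray  # (n, dim) decision vectors of the final non-dominated set
    F: np.ndarray  # (n, n_obj) objective vectors
    n_evaluations: int


def minimize_nsga3(
    objective: Callable[[np.ndarray], np.ndarray],
    n_var: int,
    lower: np.ndarray,
    upper: np.ndarray,
    pop_size: int,
    n_generations: int,
    ref_dirs: np.ndarray,
    seed: int,
    initial: np.ndarray | None = None,
    eta_crossover: float = 15.0,
    p_crossover: float = 0.9,
    eta_mutation: float = 20.0,
    p_mutation: float | None = None,
) -> NSGA3Result:
    """Run NSGA-III; returns the final non-dominated set.

    ``initial`` rows are injected into generation 0 (the remainder is drawn
    uniformly within the bounds).
    """
    rng = np.random.default_rng(seed)
    lower = np.broadcast_to(np.asarray(lower, float), (n_var,)).copy()
    upper = np.broadcast_to(np.asarray(upper, float), (n_var,)).copy()
    if pop_size < len(ref_dirs):
        raise ValueError("population must be at least the number of reference directions")
    if p_mutation is None:
        p_mutation = 1.0 / n_var

    X = rng.uniform(lower, upper, size=(pop_size, n_var))
    if initial is not None:
        initial = np.atleast_2d(initial)
        X[: len(initial)] = np.clip(initial, lower, upper)
    F = np.array([objective(x) for x in X])
    n_eval = pop_size

    for _ in range(n_generations):
        perm = rng.permutation(pop_size)
        off = sbx_crossover(X[perm], lower, upper, eta_crossover, p_crossover, rng)
        off = polynomial_mutation(off, lower, upper, eta_mutation, p_mutation, rng)
        F_off = np.array([objective(x) for x in off])
        n_eval += len(off)
        X_all = np.vstack([X, off])
        F_all = np.vstack([F, F_off])
        keep = nsga3_survival(F_all, ref_dirs, pop_size, rng)
        X, F = X_all[keep], F_all[keep]

    front = fast_nondominated_sort(F)[0]
    # deduplicate identical decision vectors for a clean front
    _, uniq = np.unique(np.round(X[front], 12), axis=0, return_index=True)
    front = front[np.sort(uniq)]
    return NSGA3Result(X[front], F[front], n_eval)
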