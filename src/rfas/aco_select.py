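"""Ant-colony short-form selection under a CFA fitness criterion.

Artificial ants build candidate item subsets per factor with probability
proportional to pheromone × heuristic (the item's full-sample EFA primary
loading).  Candidates are scored by a congeneric CFA; the iteration best
deposits pheromone after evaporation.  A local neighborhood search then
tries single-item swaps around the best solution, and a subsampling
stability analysis summarizes selection consistency with retention rates
and the mean pairwise Jaccard similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import facengine
from .facengine import FitIndices
from .synthgen import Dataset

__all__ = [
    "ACOConfig",
    "ACOState",
    "ant_construct",
    "evaluate_candidate",
    "pheromone_update",
    "aco_search",
    "local_search",
    "stability_analysis",
    "jaccard",
]


@dataclass
class ACOConfig:
    pools: dict[str, list[str]]  # factor → full item pool
    items_per_factor: dict[str, int]  # factor → target count
    n_ants: int = 15
    evaporation_keep: float = 0.85
    steps_per_run: int = 20
    max_runs: int = 150
    patience: int = 30  # runs without improvement before early stop
    screening: dict = field(
        default_factory=lambda: {"cfi_min": 0.90, "tli_min": 0.90, "rmsea_max": 0.08}
    )
    max_remove: int = 3  # local-search removal candidates per factor
    max_add: int = 5  # local-search addition candidates per factor
    pheromone_floor_ratio: float = 0.1  # max–min trail bound: τ_min = ratio · τ_max
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.evaporation_keep < 1.0:
            raise ValueError("evaporation_keep must lie in (0, 1)")
        if not 0.0 <= self.pheromone_floor_ratio < 1.0:
            raise ValueError("pheromone_floor_ratio must lie in [0, 1)")
        for f, target in self.items_per_factor.items():
            if target < 3:
                raise ValueError(f"factor {f}: at least 3 items per factor required")
            if len(self.pools.get(f, [])) < target:
                raise ValueError(
                    f"factor {f}: pool of {len(self.pools.get(f, []))} items "
                    f"cannot supply {target}"
                )

    def passes_screening(self, fit: FitIndices) -> bool:
        s = self.screening
        return (
            fit.cfi >= s["cfi_min"]
            and fit.tli >= s["tli_min"]
            and fit.rmsea <= s["rmsea_max"]
        )


@dataclass
class ACOState:
    pheromone: dict[str, float]
    heuristic: dict[str, float]
    best_solution: dict[str, list[str]] | None = None
    best_fit: FitIndices | None = None
    best_score: float = -np.inf
    history: list[dict] = field(default_factory=list)


def _score(fit: FitIndices) -> float:
    return fit.cfi + fit.tli - fit.rmsea


def init_state(data: Dataset, config: ACOConfig) -> ACOState:
    """Uniform pheromone; heuristic = |full-sample EFA primary loading|."""
    k = len(config.pools)
    sol = facengine.ml_efa(data, k)
    rot = facengine.geomin_rotate(sol, seed=config.seed)
    primary = np.abs(rot.loadings).max(axis=1)
    heuristic = {
        v: max(float(primary[data.variable_names.index(v)]), 0.05)
        for pool in config.pools.values()
        for v in pool
    }
    pheromone = {v: 1.0 for v in heuristic}
    return ACOState(pheromone=pheromone, heuristic=heuristic)


def ant_construct(
    state: ACOState, config: ACOConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """One ant's candidate: per factor, target-many distinct items sampled
    without replacement with probability ∝ pheromone × heuristic."""
    candidate: dict[str, list[str]] = {}
    for f, pool in config.pools.items():
        target = config.items_per_factor[f]
        w = np.array([state.pheromone[v] * state.heuristic[v] for v in pool])
        w = w / w.sum()
        chosen = rng.choice(len(pool), size=target, replace=False, p=w)
        candidate[f] = [pool[i] for i in sorted(chosen)]
    return candidate


def evaluate_candidate(
    candidate: dict[str, list[str]], data: Dataset, config: ACOConfig
) -> tuple[FitIndices | None, bool]:
    """Congeneric CFA of the candidate; returns (fit, passes screening).

    Non-convergence yields (None, False) so the candidate is discarded
    without touching the pheromone.
    """
    structure = {v: f for f, items in candidate.items() for v in items}
    try:
        result = facengine.cfa_fit(data, structure)
    except (ValueError, np.linalg.LinAlgError):
        return None, False
    if not result.converged:
        return None, False
    return result.fit, config.passes_screening(result.fit)


def pheromone_update(
    state: ACOState,
    iteration_best: dict[str, list[str]],
    fit: FitIndices,
    config: ACOConfig,
) -> ACOState:
    """Evaporate all trails, then deposit Δ = max(cfi + tli − rmsea, 0.01)
    on the iteration-best items.

    Trails are kept inside max–min bounds [ratio·τ_max, τ_max] with
    τ_max = Δ / (1 − evaporation_keep), the stationary level of an always
    reinforced item, so that no item's selection probability ever collapses
    to zero and the colony keeps exploring.
    """
    delta = max(_score(fit), 0.01)
    for v in state.pheromone:
        state.pheromone[v] *= config.evaporation_keep
    for items in iteration_best.values():
        for v in items:
            state.pheromone[v] += delta
    tau_max = max(delta, state.best_score) / (1.0 - config.evaporation_keep)
    tau_min = config.pheromone_floor_ratio * tau_max
    for v in state.pheromone:
        state.pheromone[v] = min(max(state.pheromone[v], tau_min), tau_max)
    return state


def aco_search(data: Dataset, config: ACOConfig) -> ACOState:
    """Global search: up to max_runs iterations of construct/evaluate/update,
    keeping the best screened candidate by cfi + tli − rmsea; early stop
    after ``patience`` runs without improvement."""
    rng = np.random.default_rng(config.seed)
    state = init_state(data, config)
    stale = 0
    any_converged = False
    # memetic initialization: hill-climb from the greedy heuristic
    # candidate (the highest-loading items per factor); the refined
    # solution becomes the incumbent when it passes screening, so the
    # colony starts from the naive short form and must beat it
    greedy = {
        f: sorted(
            sorted(pool, key=lambda v: -state.heuristic[v])[: config.items_per_factor[f]]
        )
        for f, pool in config.pools.items()
    }
    fit, _ = evaluate_candidate(greedy, data, config)
    if fit is not None:
        any_converged = True
        solution, score, fit = _hill_climb(
            greedy, _score(fit), fit, data, config, state.pheromone
        )
        if fit is not None and config.passes_screening(fit):
            state.best_score = score
            state.best_solution = solution
            state.best_fit = fit
    for run in range(config.max_runs):
        iter_best: tuple[float, dict, FitIndices] | None = None
        for _ in range(config.n_ants):
            candidate = None
            for _ in range(config.steps_per_run):  # construction budget
                candidate = ant_construct(state, config, rng)
                if candidate is not None:
                    break
            fit, screened = evaluate_candidate(candidate, data, config)
            if fit is None:
                continue
            any_converged = True
            score = _score(fit)
            if iter_best is None or score > iter_best[0]:
                iter_best = (score, candidate, fit)
            if screened and score > state.best_score:
                state.best_score = score
                state.best_solution = candidate
                state.best_fit = fit
                stale = -1
        if iter_best is not None:
            pheromone_update(state, iter_best[1], iter_best[2], config)
            state.history.append(
                {"run": run, "iter_best_score": iter_best[0], "best_score": state.best_score}
            )
        stale += 1
        if stale >= config.patience:
            break
    if not any_converged:
        raise RuntimeError("no candidate model ever converged")
    if state.best_solution is None:
        # nothing passed screening: fall back to the best converged candidate
        state.best_solution = iter_best[1] if iter_best else None
        state.best_fit = iter_best[2] if iter_best else None
        state.best_score = iter_best[0] if iter_best else -np.inf
    return state


def _hill_climb(
    solution: dict[str, list[str]],
    score: float,
    fit: FitIndices | None,
    data: Dataset,
    config: ACOConfig,
    pheromone: dict[str, float],
) -> tuple[dict[str, list[str]], float, FitIndices | None]:
    """Best-improvement single-swap climb from ``solution``.

    Per factor: up to ``max_remove`` lowest-pheromone included items may be
    swapped for up to ``max_add`` highest-pheromone unused pool items; the
    best strictly improving swap (full-data CFA score) is accepted and the
    neighborhood re-examined until a fixed point.  Item counts per factor
    never change.
    """
    while True:
        best_swap: tuple[float, dict, FitIndices] | None = None
        for f, items in solution.items():
            unused = [v for v in config.pools[f] if v not in items]
            removal = sorted(items, key=lambda v: pheromone[v])[: config.max_remove]
            addition = sorted(unused, key=lambda v: -pheromone[v])[: config.max_add]
            for out_item, in_item in itertools.product(removal, addition):
                trial = {
                    g: ([v for v in its if v != out_item] + [in_item] if g == f else list(its))
                    for g, its in solution.items()
                }
                trial_fit, _ = evaluate_candidate(trial, data, config)
                if trial_fit is None:
                    continue
                trial_score = _score(trial_fit)
                if trial_score > score and (
                    best_swap is None or trial_score > best_swap[0]
                ):
                    best_swap = (trial_score, trial, trial_fit)
        if best_swap is None:
            return solution, score, fit
        score, solution, fit = best_swap


def local_search(state: ACOState, data: Dataset, config: ACOConfig) -> ACOState:
    """Single-item swap refinement around the best solution (see
    ``_hill_climb`` for the neighborhood)."""
    if state.best_solution is None:
        raise ValueError("no best solution to refine")
    solution, score, fit = _hill_climb(
        state.best_solution, state.best_score, state.best_fit, data, config, state.pheromone
    )
    state.best_solution, state.best_score, state.best_fit = solution, score, fit
    return state


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; 1 for two empty sets."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def stability_analysis(
    data: Dataset,
    selector,
    B: int = 100,
    frac: float = 0.66,
    seed: int = 0,
) -> tuple[dict[str, float], float, int]:
    """Subsampling stability of a selection procedure.

    Runs ``selector(Dataset, seed) -> set of items`` on B subsamples of
    ``frac`` of the rows (without replacement) and returns per-item
    retention percentages, the mean pairwise Jaccard similarity of the B
    selected sets, and the number of failed replicates (excluded).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    n_sub = int(round(frac * data.n))
    solutions: list[set] = []
    failures = 0
    for b in range(B):
        idx = rng.choice(data.n, size=n_sub, replace=False)
        try:
            solutions.append(set(selector(data.rows(np.sort(idx)), int(rng.integers(2**31 - 1)))))
        except Exception:
            failures += 1
    if len(solutions) < 2:
        raise RuntimeError(f"stability analysis failed on {failures} of {B} subsamples")
    items = sorted({v for s in solutions for v in s} | set(data.variable_names))
    retention = {
        v: 100.0 * sum(v in s for s in solutions) / len(solutions) for v in items
    }
    pairs = [
        jaccard(a, b) for a, b in itertools.combinations(solutions, 2)
    ]
    return retention, float(np.mean(pairs)), failures
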