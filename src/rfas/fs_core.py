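"""Fit-and-Simple (FS) stage: per-subsample iterative variable removal and
aggregation into replicability evidence.

Each training subsample is screened by a loop that (re-)estimates the number
of factors, fits an ML EFA with geomin rotation, and removes variables that
are unimportant (no sizable primary loading), complex (a secondary loading
above threshold), insufficiently dominant (low D-score), or responsible for
model misfit.  Aggregating the per-run retention indicators over subsamples
yields each variable's replicability rating, the distribution of final
factor counts, and the per-variable "reasons" audit table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import facengine
from .facengine import EFASolution, FitIndices
from .synthgen import Dataset

__all__ = [
    "AlgorithmSettings",
    "RemovalRecord",
    "FSRunResult",
    "ReplicabilityReport",
    "d_score",
    "classify_variable",
    "fs_run",
    "fs_aggregate",
]


@dataclass
class AlgorithmSettings:
    """Every tunable of the procedure, with its default."""

    R: int = 100
    train_fraction: float = 0.66
    primary_min: float = 0.40
    secondary_max: float = 0.30
    d_min: float = 3.0
    cut: float = 0.80
    fit_thresholds: dict = field(
        default_factory=lambda: {
            "cfi_min": 0.90, "tli_min": 0.90, "srmr_max": 0.10, "rmsea_max": 0.10,
        }
    )
    report_thresholds: dict = field(
        default_factory=lambda: {
            "cfi_min": 0.95, "tli_min": 0.95, "rmsea_max": 0.08, "srmr_max": 0.08,
        }
    )
    removal_mode: str = "sequential"  # "sequential" | "tandem"
    k_method: str = "parallel_analysis"  # "parallel_analysis" | "ega"
    geomin_epsilon: float = 0.01
    rotation_starts: int = 10
    pa_reps: int = 100
    pa_percentile: float = 95.0
    ega_gamma: float = 0.5
    min_vars_per_factor: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cut <= 1.0:
            raise ValueError("cut must lie in (0, 1]")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.removal_mode not in ("sequential", "tandem"):
            raise ValueError(f"unknown removal_mode {self.removal_mode!r}")
        if self.k_method not in ("parallel_analysis", "ega"):
            raise ValueError(f"unknown k_method {self.k_method!r}")

    def _passes_fit(self, fit: FitIndices) -> bool:
        t = self.fit_thresholds
        return fit.passes(t["cfi_min"], t["tli_min"], t["rmsea_max"], t["srmr_max"])


@dataclass
class RemovalRecord:
    variable: str
    iteration: int
    reason: str  # "unimportant" | "complex" | "low_d" | "misfit"
    k_at_removal: int


@dataclass
class FSRunResult:
    retained: list[str]
    k_final: int
    removals: list[RemovalRecord]
    final_fit: FitIndices | None
    stopped_single_factor: bool = False
    aborted: bool = False
    diagnostic: str = ""


@dataclass
class ReplicabilityReport:
    rating: dict[str, float]
    k_distribution: dict[int, float]
    reasons_table: dict[str, Counter]
    final_variables: list[str]
    final_k: int
    factor_replicability: float
    n_runs: int
    n_aborted: int
    mean_final_fit: FitIndices | None = None


def d_score(loadings_row: np.ndarray) -> float:
    """Dominance ratio D = λ_p² / Σ_{s≠p} λ_s².

    λ_p is the largest-magnitude entry; a row with no nonzero secondary
    (including every single-factor row) has D = +∞, and an all-zero row is
    reported as 0.
    """
    row = np.asarray(loadings_row, dtype=float)
    p = int(np.argmax(np.abs(row)))
    primary = row[p]
    if primary == 0.0:
        return 0.0
    sec = np.delete(row, p)
    denom = float(np.sum(sec**2))
    if denom == 0.0:
        return math.inf
    return float(primary**2 / denom)


def classify_variable(loadings_row: np.ndarray, settings: AlgorithmSettings) -> str:
    """Retention status with precedence unimportant → complex → low_d."""
    row = np.asarray(loadings_row, dtype=float)
    p = int(np.argmax(np.abs(row)))
    if abs(row[p]) < settings.primary_min:
        return "unimportant"
    sec = np.abs(np.delete(row, p))
    if sec.size and sec.max() > settings.secondary_max:
        return "complex"
    if d_score(row) < settings.d_min:
        return "low_d"
    return "retain"


def _estimate_k(data: Dataset, settings: AlgorithmSettings, rng: np.random.Generator) -> int:
    seed = int(rng.integers(2**31 - 1))
    if settings.k_method == "parallel_analysis":
        return facengine.parallel_analysis(
            data, n_reps=settings.pa_reps, percentile=settings.pa_percentile, seed=seed
        )
    return facengine.ega_factor_count(data, gamma=settings.ega_gamma, seed=seed)


def _max_feasible_k(p: int) -> int:
    k = 1
    while k + 1 < p and ((p - (k + 1)) ** 2 - p - (k + 1)) // 2 >= 0:
        k += 1
    return k


def _fit_rotated(
    data: Dataset, k: int, settings: AlgorithmSettings, rng: np.random.Generator
) -> EFASolution:
    sol = facengine.ml_efa(data, k)
    return facengine.geomin_rotate(
        sol,
        epsilon=settings.geomin_epsilon,
        n_starts=settings.rotation_starts,
        seed=int(rng.integers(2**31 - 1)),
    )


def _worst_misfit_variable(data: Dataset, sol: EFASolution) -> str:
    """Variable with the largest sum of squared residual correlations."""
    residual = data.corr() - sol.implied_corr()
    np.fill_diagonal(residual, 0.0)
    mass = (residual**2).sum(axis=0)
    return data.variable_names[int(np.argmax(mass))]


def _single_factor_stage(
    data: Dataset,
    settings: AlgorithmSettings,
    rng: np.random.Generator,
    removals: list[RemovalRecord],
    iteration: int,
) -> FSRunResult:
    """One-factor endgame: prune below-threshold loadings only, then stop."""
    current = data
    fit = None
    while current.p >= 3:
        sol = _fit_rotated(current, 1, settings, rng)
        fit = sol.fit
        lam = np.abs(sol.loadings[:, 0])
        if lam.min() >= settings.primary_min:
            break
        victim = current.variable_names[int(np.argmin(lam))]
        removals.append(RemovalRecord(victim, iteration, "unimportant", 1))
        iteration += 1
        if current.p - 1 < 3:
            current = current.subset([v for v in current.variable_names if v != victim])
            break
        current = current.subset([v for v in current.variable_names if v != victim])
    return FSRunResult(
        retained=list(current.variable_names),
        k_final=1,
        removals=removals,
        final_fit=fit,
        stopped_single_factor=True,
    )


def fs_run(training: Dataset, settings: AlgorithmSettings, seed: int | None = None) -> FSRunResult:
    """Run the FS removal loop on one training subsample.

    The loop re-estimates the factor count each iteration, fits ML EFA with
    geomin rotation, removes variables for misfit or rule violations
    (sequentially or in tandem), and drops factors that own fewer than
    ``min_vars_per_factor`` variables.  A persistent cap keeps a dropped
    factor from being re-introduced by the factor-count method.  With a
    single factor the loop switches to a primary-loading-only endgame.
    """
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    current = training
    removals: list[RemovalRecord] = []
    k_cap: int | None = None
    iteration = 0
    try:
        while True:
            iteration += 1
            if current.p < 3:
                return FSRunResult(
                    retained=list(current.variable_names),
                    k_final=1,
                    removals=removals,
                    final_fit=None,
                    aborted=True,
                    diagnostic="fewer than 3 variables remain",
                )
            k = _estimate_k(current, settings, rng)
            k = min(k, _max_feasible_k(current.p))
            if k_cap is not None:
                k = min(k, k_cap)
            k = max(k, 1)
            if k == 1:
                return _single_factor_stage(current, settings, rng, removals, iteration)

            sol = _fit_rotated(current, k, settings, rng)
            if not settings._passes_fit(sol.fit):
                victim = _worst_misfit_variable(current, sol)
                removals.append(RemovalRecord(victim, iteration, "misfit", k))
                current = current.subset(
                    [v for v in current.variable_names if v != victim]
                )
                continue

            statuses = [
                classify_variable(sol.loadings[i], settings) for i in range(current.p)
            ]
            flagged = [
                (v, s, sol.loadings[i])
                for i, (v, s) in enumerate(zip(current.variable_names, statuses))
                if s != "retain"
            ]
            removed_now: list[str] = []
            if flagged:
                if settings.removal_mode == "tandem":
                    for v, s, _ in flagged:
                        removals.append(RemovalRecord(v, iteration, s, k))
                        removed_now.append(v)
                else:
                    removed_now.append(_sequential_victim(flagged, removals, iteration, k))
                current = current.subset(
                    [v for v in current.variable_names if v not in removed_now]
                )

            # factor-ownership check on the retained rows of this solution
            keep_idx = [
                i for i, v in enumerate(sol.variable_names or training.variable_names)
                if v not in removed_now
            ] if removed_now else list(range(sol.loadings.shape[0]))
            primary = np.abs(sol.loadings).argmax(axis=1)
            owners = Counter(primary[i] for i in keep_idx)
            deficient = sum(
                1 for f in range(k) if owners.get(f, 0) < settings.min_vars_per_factor
            )
            if deficient:
                k_cap = max(k - deficient, 1)
                continue
            if not flagged:
                return FSRunResult(
                    retained=list(current.variable_names),
                    k_final=k,
                    removals=removals,
                    final_fit=sol.fit,
                )
    except (np.linalg.LinAlgError, ValueError) as exc:
        return FSRunResult(
            retained=list(current.variable_names),
            k_final=0,
            removals=removals,
            final_fit=None,
            aborted=True,
            diagnostic=f"estimation failure: {exc}",
        )


def _sequential_victim(flagged, removals, iteration, k) -> str:
    """Pick one variable: unimportant (smallest |λ_p|), else complex
    (largest secondary), else low_d (smallest D)."""
    by_status = {s: [f for f in flagged if f[1] == s] for s in ("unimportant", "complex", "low_d")}
    if by_status["unimportant"]:
        v, s, row = min(
            by_status["unimportant"], key=lambda f: np.abs(f[2]).max()
        )
    elif by_status["complex"]:
        def worst_secondary(f):
            row = np.asarray(f[2])
            p = int(np.argmax(np.abs(row)))
            return np.abs(np.delete(row, p)).max()
        v, s, row = max(by_status["complex"], key=worst_secondary)
    else:
        v, s, row = min(by_status["low_d"], key=lambda f: d_score(f[2]))
    removals.append(RemovalRecord(v, iteration, s, k))
    return v


def fs_aggregate(
    results: list[FSRunResult], settings: AlgorithmSettings
) -> ReplicabilityReport:
    """Aggregate per-run outcomes into replicability evidence.

    Aborted runs are excluded from denominators but counted.  The modal
    factor count breaks ties toward fewer factors.
    """
    good = [r for r in results if not r.aborted]
    n_aborted = len(results) - len(good)
    if not good:
        diags = "; ".join(r.diagnostic for r in results if r.aborted)
        raise RuntimeError(f"no successful runs to aggregate: {diags}")
    all_vars: list[str] = []
    for r in good:
        for v in r.retained + [rec.variable for rec in r.removals]:
            if v not in all_vars:
                all_vars.append(v)
    R = len(good)
    rating = {v: sum(v in r.retained for r in good) / R for v in all_vars}
    reasons: dict[str, Counter] = {v: Counter() for v in all_vars}
    for r in good:
        for rec in r.removals:
            reasons[rec.variable][rec.reason] += 1
    k_counts = Counter(r.k_final for r in good)
    k_distribution = {k: c / R for k, c in sorted(k_counts.items())}
    final_k = min(
        (k for k, c in k_counts.items() if c == max(k_counts.values()))
    )
    final_variables = [v for v in all_vars if rating[v] >= settings.cut]
    fits = [r.final_fit for r in good if r.final_fit is not None]
    mean_fit = None
    if fits:
        mean_fit = FitIndices(
            chi2=float(np.mean([f.chi2 for f in fits])),
            df=int(round(np.mean([f.df for f in fits]))),
            chi2_baseline=float(np.mean([f.chi2_baseline for f in fits])),
            df_baseline=int(round(np.mean([f.df_baseline for f in fits]))),
            cfi=float(np.mean([f.cfi for f in fits])),
            tli=float(np.mean([f.tli for f in fits])),
            rmsea=float(np.mean([f.rmsea for f in fits])),
            srmr=float(np.mean([f.srmr for f in fits])),
            n=int(round(np.mean([f.n for f in fits]))),
        )
    return ReplicabilityReport(
        rating=rating,
        k_distribution=k_distribution,
        reasons_table=reasons,
        final_variables=final_variables,
        final_k=final_k,
        factor_replicability=k_distribution[final_k],
        n_runs=R,
        n_aborted=n_aborted,
        mean_final_fit=mean_fit,
    )
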