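"""Replicable Fit-and-Simple (RFS) stage: confirmatory cross-validation.

The variable set surviving the replicability cut is turned into a single
congeneric CFA structure (each variable assigned to its strongest factor in
a full-sample EFA) and re-estimated on every validation subsample.  The
averaged fit indices are judged against the stricter reporting thresholds,
and large factor correlations are flagged as multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import facengine
from .facengine import CFAResult, FitIndices
from .fs_core import AlgorithmSettings
from .synthgen import Dataset

__all__ = ["RFSReport", "build_cfa_structure", "rfs_validate"]

MULTICOLLINEARITY_R = 0.70


@dataclass
class RFSReport:
    per_subsample: list[CFAResult]
    mean_fit: FitIndices | None
    mean_loadings: dict[str, float]
    mean_factor_corr: np.ndarray | None
    verdict: str  # "pass" | "fail" | "unstable"
    multicollinearity_flag: bool
    n_failures: int


def build_cfa_structure(
    final_variables: list[str],
    final_k: int,
    full_data: Dataset,
    settings: AlgorithmSettings | None = None,
) -> dict[str, str]:
    """Assign each surviving variable to its strongest factor.

    Fits one ML EFA with geomin rotation at ``final_k`` on the full dataset
    restricted to the surviving variables and assigns each variable to the
    factor carrying its largest-|loading|.  Refuses when a factor ends up
    with fewer than 3 variables (the caller may decrement k and retry).
    """
    settings = settings or AlgorithmSettings()
    if final_k < 1:
        raise ValueError("final_k must be at least 1")
    if len(final_variables) < 3 * final_k:
        raise ValueError(
            f"{len(final_variables)} variables cannot support {final_k} factors "
            "with 3 indicators each"
        )
    if final_k == 1:
        return {v: "F1" for v in final_variables}
    sub = full_data.subset(list(final_variables))
    sol = facengine.ml_efa(sub, final_k)
    rot = facengine.geomin_rotate(
        sol,
        epsilon=settings.geomin_epsilon,
        n_starts=settings.rotation_starts,
        seed=settings.seed,
    )
    assignment = np.abs(rot.loadings).argmax(axis=1)
    sizes = {f: int(np.sum(assignment == f)) for f in range(final_k)}
    if min(sizes.values()) < settings.min_vars_per_factor:
        raise ValueError(f"assignment leaves under-identified factors: sizes {sizes}")
    return {
        v: f"F{assignment[i] + 1}" for i, v in enumerate(sub.variable_names)
    }


def rfs_validate(
    splits: list[tuple[np.ndarray, np.ndarray]],
    structure: dict[str, str],
    data: Dataset,
    settings: AlgorithmSettings,
) -> RFSReport:
    """Congeneric CFA of ``structure`` on each validation subsample.

    Convergence failures are excluded from the means and counted; more than
    50% failures yields the verdict "unstable".  The pass/fail verdict uses
    the averaged indices against the reporting thresholds.
    """
    results: list[CFAResult] = []
    n_fail = 0
    for _, validation in splits:
        sub = data.rows(validation)
        try:
            res = facengine.cfa_fit(sub, structure)
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        if not res.converged:
            n_fail += 1
            continue
        results.append(res)
    if not results or n_fail > len(splits) / 2:
        return RFSReport(
            per_subsample=results,
            mean_fit=None,
            mean_loadings={},
            mean_factor_corr=None,
            verdict="unstable",
            multicollinearity_flag=False,
            n_failures=n_fail,
        )
    variables = list(structure)
    mean_loadings = {
        v: float(np.mean([r.loadings[v] for r in results])) for v in variables
    }
    mean_phi = np.mean([r.factor_corr for r in results], axis=0)
    fields = ("chi2", "cfi", "tli", "rmsea", "srmr")
    means = {f: float(np.mean([getattr(r.fit, f) for r in results])) for f in fields}
    f0 = results[0].fit
    mean_fit = FitIndices(
        chi2=means["chi2"],
        df=f0.df,
        chi2_baseline=float(np.mean([r.fit.chi2_baseline for r in results])),
        df_baseline=f0.df_baseline,
        cfi=means["cfi"],
        tli=means["tli"],
        rmsea=means["rmsea"],
        srmr=means["srmr"],
        n=f0.n,
    )
    t = settings.report_thresholds
    verdict = (
        "pass"
        if mean_fit.passes(t["cfi_min"], t["tli_min"], t["rmsea_max"], t["srmr_max"])
        else "fail"
    )
    off = mean_phi[~np.eye(mean_phi.shape[0], dtype=bool)]
    multi = bool(off.size and np.max(np.abs(off)) > MULTICOLLINEARITY_R)
    return RFSReport(
        per_subsample=results,
        mean_fit=mean_fit,
        mean_loadings=mean_loadings,
        mean_factor_corr=mean_phi,
        verdict=verdict,
        multicollinearity_flag=multi,
        n_failures=n_fail,
    )
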