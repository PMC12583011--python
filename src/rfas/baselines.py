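"""Stepwise selection baselines and method-comparison statistics.

Two stepwise EFA baselines remove variables to improve the Tucker–Lewis
index (either until a target TLI is reached or while the improvement per
removal stays above a minimum), and a small set of statistics compares
variable-retention profiles between selection methods: the share of
variables retained in over 80% of subsamples, a pooled two-sample t with
Cohen's d, and the Pearson agreement between retention columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import facengine
from .synthgen import Dataset

__all__ = [
    "stepwise_select",
    "retention_over_threshold",
    "pooled_t_and_d",
    "method_agreement",
    "ComparisonStats",
]

TLI_TARGET_DEFAULT = 0.95
DELTA_TLI_DEFAULT = 0.01


@dataclass
class ComparisonStats:
    t: float
    df: int
    p: float
    d: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float


def _tli(data: Dataset, k: int) -> float:
    return facengine.ml_efa(data, k).fit.tli


def stepwise_select(
    data: Dataset,
    k: int,
    mode: str = "tli_target",
    target: float = TLI_TARGET_DEFAULT,
    delta_min: float = DELTA_TLI_DEFAULT,
) -> list[str]:
    """Stepwise variable removal under an EFA TLI criterion with fixed k.

    ``tli_target``: stop as soon as the current TLI reaches ``target``,
    otherwise remove the variable whose removal maximizes TLI.
    ``delta_tli``: keep removing while the best single removal improves TLI
    by at least ``delta_min``.  Never drops below 3 variables per factor.
    """
    if mode not in ("tli_target", "delta_tli"):
        raise ValueError(f"unknown mode {mode!r}")
    current = data
    while current.p > 3 * k:
        tli_now = _tli(current, k)
        if mode == "tli_target" and tli_now >= target:
            break
        best_var, best_tli = None, -math.inf
        for v in current.variable_names:
            reduced = current.subset([w for w in current.variable_names if w != v])
            try:
                t = _tli(reduced, k)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if t > best_tli:
                best_var, best_tli = v, t
        if best_var is None:
            break
        if mode == "delta_tli" and best_tli - tli_now < delta_min:
            break
        if mode == "tli_target" and best_tli <= tli_now and tli_now >= target:
            break
        current = current.subset([w for w in current.variable_names if w != best_var])
    return list(current.variable_names)


def retention_over_threshold(column, threshold: float = 80.0) -> float:
    """Percentage of retention values at or above the threshold, rounded
    half-up to a whole percent."""
    values = np.asarray(column, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("column is empty")
    pct = 100.0 * np.sum(values >= threshold) / values.size
    return float(math.floor(pct + 0.5))


def pooled_t_and_d(x, y) -> ComparisonStats:
    """Two-sample pooled-variance t test and Cohen's d.

    d uses s_pooled = √((s_x² + s_y²)/2) for equal group sizes and the
    df-weighted pooled form otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: t and d are undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    s_d = math.sqrt((vx + vy) / 2.0) if nx == ny else math.sqrt(sp2)
    d = (x.mean() - y.mean()) / s_d
    return ComparisonStats(
        t=float(t),
        df=int(df),
        p=float(p),
        d=float(d),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(math.sqrt(vx)),
        sd_y=float(math.sqrt(vy)),
    )


def method_agreement(col_a, col_b) -> float:
    """Pearson correlation between two retention columns."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("columns must have equal length of at least 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a column: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
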