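"""Population factor models and multivariate-normal data generation.

A simulated condition is summarized the way factor-analytic simulation
studies usually report it: number of factors (NF), number of observed
variables (NV), primary loadings per factor, structure class (approximately
simple vs. complex), mean primary and mean secondary loading, and a single
interfactor correlation.  :func:`build_loading_matrix` expands such a summary
into a full population model (Λ, Φ, ψ) whose implied correlation matrix has
unit diagonal, and :func:`simulate_dataset` draws data from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FactorModelSpec",
    "Dataset",
    "HeywoodError",
    "build_loading_matrix",
    "residual_variance",
    "simulate_dataset",
    "split_subsamples",
    "STUDY_MODELS",
    "study_model_spec",
]

#: half-width of the uniform interval primary loadings are drawn from
PRIMARY_SPREAD = 0.12
#: fraction of variables that receive one large secondary loading in
#: complex structures, and the interval it is drawn from
COMPLEX_FRACTION = 0.25
COMPLEX_RANGE = (0.30, 0.45)


class HeywoodError(ValueError):
    """A loading row implies non-positive residual variance."""


@dataclass
class FactorModelSpec:
    """Population factor model for one simulated condition.

    Until :func:`build_loading_matrix` is applied, ``loading_matrix``,
    ``factor_corr`` and ``residuals`` may be ``None`` (summary-only spec).
    """

    n_factors: int
    n_variables: int
    primaries_per_factor: list[int]
    structure: str  # "approximate_simple" | "complex"
    mean_primary: float
    mean_secondary: float
    interfactor_r: float
    loading_matrix: np.ndarray | None = None
    factor_corr: np.ndarray | None = None
    residuals: np.ndarray | None = None
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_variables < 3:
            raise ValueError("at least 3 observed variables are required")
        if sum(self.primaries_per_factor) != self.n_variables:
            raise ValueError(
                "primaries_per_factor must sum to n_variables "
                f"({self.primaries_per_factor} vs {self.n_variables})"
            )
        if len(self.primaries_per_factor) != self.n_factors:
            raise ValueError("one primary count per factor is required")
        if self.structure not in ("approximate_simple", "complex"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not 0.0 < self.mean_primary < 1.0:
            raise ValueError("mean_primary must lie in (0, 1)")
        if not 0.0 <= self.mean_secondary < 1.0:
            raise ValueError("mean_secondary must lie in [0, 1)")
        if not 0.0 <= self.interfactor_r < 1.0:
            raise ValueError("interfactor_r must lie in [0, 1)")
        if not self.variable_names:
            self.variable_names = [f"X{i + 1}" for i in range(self.n_variables)]

    # -- derived quantities -------------------------------------------------

    @property
    def primary_factor(self) -> np.ndarray:
        """Index of the factor carrying each variable's primary loading."""
        return np.repeat(np.arange(self.n_factors), self.primaries_per_factor)

    def implied_corr(self) -> np.ndarray:
        """Population correlation matrix Λ Φ Λᵀ + diag(ψ)."""
        if self.loading_matrix is None:
            raise ValueError("spec has no loading matrix; run build_loading_matrix")
        lam, phi = self.loading_matrix, self.factor_corr
        return lam @ phi @ lam.T + np.diag(self.residuals)


@dataclass
class Dataset:
    """An n × p numeric data table with variable names."""

    values: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if np.isnan(self.values).any():
            raise ValueError("missing entries are not supported")
        if self.values.shape[1] != len(self.variable_names):
            raise ValueError("one name per column is required")
        if self.values.shape[1] < 3:
            raise ValueError("at least 3 variables are required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def corr(self) -> np.ndarray:
        return np.corrcoef(self.values, rowvar=False)

    def subset(self, names: list[str]) -> "Dataset":
        idx = [self.variable_names.index(v) for v in names]
        return Dataset(self.values[:, idx], list(names))

    def rows(self, index: np.ndarray) -> "Dataset":
        return Dataset(self.values[index], list(self.variable_names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        frame = pd.read_csv(path)
        return cls(frame.to_numpy(dtype=float), list(frame.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def residual_variance(loadings_row: np.ndarray, factor_corr: np.ndarray) -> float:
    """Residual variance ψ = 1 − λᵀΦλ for one variable.

    Raises :class:`HeywoodError` when the communality reaches or exceeds 1.
    """
    lam = np.asarray(loadings_row, dtype=float)
    phi = np.asarray(factor_corr, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("loading magnitudes must be below 1")
    psi = 1.0 - float(lam @ phi @ lam)
    if psi <= 0:
        raise HeywoodError(
            f"row {np.round(lam, 3).tolist()} implies non-positive residual "
            f"variance ψ={psi:.4f}"
        )
    return psi


def _compound_symmetric(k: int, rho: float) -> np.ndarray:
    phi = np.full((k, k), rho, dtype=float)
    np.fill_diagonal(phi, 1.0)
    return phi


def _draw_row(
    spec: FactorModelSpec, var: int, is_complex_row: bool, rng: np.random.Generator
) -> tuple[float, np.ndarray, int | None, float]:
    """Raw (unrecentred) draws for one variable's loading row.

    Returns (primary value, small-secondary values for the other factors,
    position of the large secondary among those, large-secondary value).
    """
    mp, ms = spec.mean_primary, spec.mean_secondary
    primary = rng.uniform(mp - PRIMARY_SPREAD, mp + PRIMARY_SPREAD)
    n_sec = spec.n_factors - 1
    smalls = rng.uniform(0.0, 2.0 * ms, size=n_sec) * rng.choice([-1.0, 1.0], n_sec)
    big_pos: int | None = None
    big_val = 0.0
    if is_complex_row and n_sec:
        big_pos = int(rng.integers(n_sec))
        big_val = rng.uniform(*COMPLEX_RANGE) * rng.choice([-1.0, 1.0])
    return primary, smalls, big_pos, big_val


def build_loading_matrix(spec: FactorModelSpec, seed: int) -> FactorModelSpec:
    """Expand a summary spec into a full population model.

    Primary loadings are drawn uniformly on ``[MP − 0.12, MP + 0.12]`` and
    shifted so their mean equals MP exactly.  Small secondary loadings are
    drawn on ``[0, 2·MS]`` with random signs; for complex structures 25% of
    variables additionally receive one large secondary on ±[0.30, 0.45].
    The small secondaries are rescaled so the mean absolute secondary equals
    MS exactly.  Rows implying a Heywood case are redrawn (with recentring
    re-applied) up to a retry cap.
    """
    if spec.mean_primary <= spec.mean_secondary:
        raise ValueError("mean_primary must exceed mean_secondary")
    rng = np.random.default_rng(seed)
    p, k = spec.n_variables, spec.n_factors
    phi = _compound_symmetric(k, spec.interfactor_r)
    owner = spec.primary_factor

    n_complex = max(1, round(COMPLEX_FRACTION * p)) if spec.structure == "complex" else 0
    complex_rows = set(rng.choice(p, size=n_complex, replace=False).tolist()) if n_complex else set()

    draws = [_draw_row(spec, i, i in complex_rows, rng) for i in range(p)]

    def assemble() -> tuple[np.ndarray, np.ndarray]:
        lam = np.zeros((p, k))
        primaries = np.array([d[0] for d in draws])
        primaries = primaries + (spec.mean_primary - primaries.mean())
        big_total = 0.0
        small_total = 0.0
        for i, (_, smalls, big_pos, big_val) in enumerate(draws):
            small_total += np.abs(smalls).sum()
            if big_pos is not None:
                small_total -= abs(smalls[big_pos])
                big_total += abs(big_val)
        n_cells = p * (k - 1)
        if k > 1 and small_total > 0:
            scale = (spec.mean_secondary * n_cells - big_total) / small_total
            if scale < 0:
                raise ValueError(
                    "mean_secondary too small for the complex-loading fraction"
                )
        else:
            scale = 0.0
        for i, (_, smalls, big_pos, big_val) in enumerate(draws):
            others = [f for f in range(k) if f != owner[i]]
            row = smalls * scale
            if big_pos is not None:
                row[big_pos] = big_val
            lam[i, others] = row
            lam[i, owner[i]] = primaries[i]
        psi = 1.0 - np.einsum("ij,jk,ik->i", lam, phi, lam)
        return lam, psi

    for _ in range(100):
        lam, psi = assemble()
        bad = np.flatnonzero(psi < 0.01)
        if bad.size == 0:
            break
        for i in bad:
            draws[i] = _draw_row(spec, i, i in complex_rows, rng)
    else:
        raise HeywoodError(
            f"could not construct admissible residuals for rows {bad.tolist()} "
            f"after 100 redraws (MP={spec.mean_primary}, ρ={spec.interfactor_r})"
        )

    implied = lam @ phi @ lam.T + np.diag(psi)
    if np.linalg.eigvalsh(implied).min() <= 1e-8:
        raise HeywoodError("implied correlation matrix is not positive definite")
    return replace(spec, loading_matrix=lam, factor_corr=phi, residuals=psi)


def simulate_dataset(spec: FactorModelSpec, n: int, seed: int) -> Dataset:
    """Draw ``n`` observations from the spec's multivariate-normal population."""
    if spec.loading_matrix is None:
        raise ValueError("spec has no loading matrix; run build_loading_matrix")
    if n < spec.n_variables:
        raise ValueError(f"n={n} is below the number of variables p={spec.n_variables}")
    sigma = spec.implied_corr()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    values = rng.standard_normal((n, spec.n_variables)) @ chol.T
    return Dataset(values, list(spec.variable_names))


def split_subsamples(
    data: Dataset, R: int, train_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """R independent training/validation partitions of the rows.

    Training size is ``round(train_fraction · n)``; each row falls in exactly
    one of the two sets per partition (sampling without replacement).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if R < 1:
        raise ValueError("R must be at least 1")
    n_train = int(round(train_fraction * data.n))
    if n_train < data.p:
        raise ValueError(
            f"training size {n_train} is below the number of variables {data.p} "
            f"(n={data.n}, train_fraction={train_fraction})"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(R):
        perm = rng.permutation(data.n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


# -- Table-style condition summaries ---------------------------------------

#: the six model summaries used throughout the package's simulation studies:
#: (NF, NV, primaries per factor, structure, MP, MS)
STUDY_MODELS: dict[str, tuple] = {
    "model1": (4, 40, [10, 10, 10, 10], "approximate_simple", 0.56, 0.08),
    "model2": (4, 40, [10, 10, 10, 10], "approximate_simple", 0.55, 0.12),
    "model3": (4, 26, [17, 5, 2, 2], "approximate_simple", 0.63, 0.09),
    "model4": (4, 20, [5, 5, 5, 5], "approximate_simple", 0.58, 0.14),
    "model5": (4, 40, [10, 10, 10, 10], "complex", 0.62, 0.15),
    "model6": (4, 26, [14, 4, 4, 4], "complex", 0.60, 0.15),
}


def study_model_spec(name: str, interfactor_r: float) -> FactorModelSpec:
    """Summary spec for one of the six study factor models."""
    nf, nv, plpf, structure, mp, ms = STUDY_MODELS[name]
    return FactorModelSpec(
        n_factors=nf,
        n_variables=nv,
        primaries_per_factor=list(plpf),
        structure=structure,
        mean_primary=mp,
        mean_secondary=ms,
        interfactor_r=interfactor_r,
    )
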