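"""Shared builders for small synthetic factor-model datasets."""

from __future__ import annotations

import numpy as np

from rfas.synthgen import Dataset


def population_corr(loadings: np.ndarray, factor_corr: np.ndarray) -> np.ndarray:
    """ΛΦΛᵀ with residuals completing a unit diagonal."""
    lam = np.asarray(loadings, dtype=float)
    phi = np.asarray(factor_corr, dtype=float)
    common = lam @ phi @ lam.T
    return common + np.diag(1.0 - np.diag(common))


def sample_from_corr(
    sigma: np.ndarray, n: int, seed: int, names: list[str] | None = None
) -> Dataset:
    """Multivariate-normal sample with the given population correlation."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)
    values = rng.standard_normal((n, sigma.shape[0])) @ chol.T
    if names is None:
        names = [f"V{i + 1}" for i in range(sigma.shape[0])]
    return Dataset(values, names)


def clean_two_factor(
    n: int = 500,
    seed: int = 0,
    loading: float = 0.7,
    rho: float = 0.3,
    per_factor: int = 4,
) -> Dataset:
    """Sample from an exact two-factor simple structure."""
    p = 2 * per_factor
    lam = np.zeros((p, 2))
    lam[:per_factor, 0] = loading
    lam[per_factor:, 1] = loading
    phi = np.array([[1.0, rho], [rho, 1.0]])
    return sample_from_corr(population_corr(lam, phi), n, seed)


# -- contaminated item-pool toy for short-form selection --------------------
#
# Two factors, pools of six items each.  Per pool: two strong clean markers
# (0.75), one weaker clean marker (0.65), and three contaminated items whose
# loadings are split across both factors in three different mixtures.  The
# heterogeneous mixtures make every candidate containing a contaminated item
# misfit a two-factor congeneric CFA, so the six clean items are the unique
# population optimum; the weaker clean marker keeps the naive
# highest-loading heuristic from finding it on its own.

CONTAMINATION_MIXES = [(0.70, 0.30), (0.30, 0.70), (0.50, 0.50)]
CLEAN_LOADINGS = [0.75, 0.75, 0.65]
CLEAN_ITEMS = {"V1", "V2", "V3", "V7", "V8", "V9"}


def contaminated_pools_dataset(seed: int, n: int = 600) -> Dataset:
    lam = np.zeros((12, 2))
    for j, i in enumerate((0, 1, 2)):
        lam[i, 0] = CLEAN_LOADINGS[j]
    for j, i in enumerate((6, 7, 8)):
        lam[i, 1] = CLEAN_LOADINGS[j]
    for j, i in enumerate((3, 4, 5)):
        lam[i] = CONTAMINATION_MIXES[j]
    for j, i in enumerate((9, 10, 11)):
        lam[i] = CONTAMINATION_MIXES[j][::-1]
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    return sample_from_corr(population_corr(lam, phi), n, seed)
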