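"""Estimation backbone: ML factor analysis, geomin rotation, fit indices,
and factor-count methods.

Exploratory fits use the profile maximum-likelihood algorithm (optimizing
the uniquenesses with the loadings concentrated out through the eigen
decomposition of Ψ^{-1/2} R Ψ^{-1/2}).  Oblique geomin rotation is done by
the gradient-projection algorithm with random starts.  Confirmatory fits
estimate a congeneric model (one loading per variable, free factor
correlations, independent residuals) by direct minimization of the ML
discrepancy.  Factor counts come from parallel analysis (eigenvalues vs.
random-data percentiles) or from a regularized partial-correlation network
with Walktrap communities (exploratory graph analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .synthgen import Dataset

__all__ = [
    "FitIndices",
    "EFASolution",
    "CFAResult",
    "ml_efa",
    "geomin_rotate",
    "fit_indices",
    "parallel_analysis",
    "ega_factor_count",
    "cfa_fit",
    "align_to_reference",
    "tucker_congruence",
]

UNIQUENESS_FLOOR = 0.005


@dataclass
class FitIndices:
    """Global fit of one factor model under ML estimation."""

    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n: int

    def passes(self, cfi_min: float, tli_min: float, rmsea_max: float, srmr_max: float) -> bool:
        return (
            self.cfi >= cfi_min
            and self.tli >= tli_min
            and self.rmsea <= rmsea_max
            and self.srmr <= srmr_max
        )


@dataclass
class EFASolution:
    k: int
    loadings: np.ndarray  # p × k pattern matrix
    factor_corr: np.ndarray  # k × k Φ
    uniquenesses: np.ndarray
    fit: FitIndices
    converged: bool
    heywood: bool = False
    variable_names: list[str] | None = None

    def implied_corr(self) -> np.ndarray:
        return (
            self.loadings @ self.factor_corr @ self.loadings.T
            + np.diag(self.uniquenesses)
        )


@dataclass
class CFAResult:
    loadings: dict[str, float]
    factor_of: dict[str, str]
    factor_corr: np.ndarray
    factor_names: list[str]
    residuals: dict[str, float]
    fit: FitIndices
    converged: bool


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def fit_indices(
    chi2: float,
    df: int,
    chi2_baseline: float,
    df_baseline: int,
    n: int,
    residual_corr: np.ndarray,
) -> FitIndices:
    """CFI, TLI, RMSEA and SRMR from chi-square statistics and residuals.

    Saturated models (df = 0) get CFI = TLI = 1 and RMSEA = 0.  SRMR is the
    root mean square of the lower-triangular residual correlations, diagonal
    included.
    """
    if df_baseline <= 0:
        raise ValueError("df_baseline must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    if df == 0:
        tli = 1.0
        rmsea = 0.0
    else:
        base_ratio = chi2_baseline / df_baseline
        tli = (base_ratio - chi2 / df) / (base_ratio - 1.0)
        rmsea = float(np.sqrt(excess / (df * (n - 1))))
    res = np.asarray(residual_corr, dtype=float)
    tril = res[np.tril_indices(res.shape[0])]
    srmr = float(np.sqrt(np.mean(tril**2)))
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        chi2_baseline=float(chi2_baseline),
        df_baseline=int(df_baseline),
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=float(tli),
        rmsea=rmsea,
        srmr=srmr,
        n=int(n),
    )


def _as_corr(data_or_corr, n: int | None):
    """Accept a Dataset or an explicit (correlation matrix, n) pair."""
    if isinstance(data_or_corr, Dataset):
        return data_or_corr.corr(), data_or_corr.n, list(data_or_corr.variable_names)
    corr = np.asarray(data_or_corr, dtype=float)
    if n is None:
        raise ValueError("n must be supplied with a correlation matrix")
    return corr, n, [f"X{i + 1}" for i in range(corr.shape[0])]


def _baseline_chi2(corr: np.ndarray, n: int) -> tuple[float, int]:
    p = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    return -(n - 1) * logdet, p * (p - 1) // 2


# ---------------------------------------------------------------------------
# exploratory ML factor analysis
# ---------------------------------------------------------------------------

def _efa_loadings(corr: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Conditionally optimal loadings given uniquenesses."""
    d = 1.0 / np.sqrt(psi)
    m = corr * np.outer(d, d)
    theta, vec = np.linalg.eigh(m)
    top = np.argsort(theta)[::-1][:k]
    gain = np.sqrt(np.maximum(theta[top] - 1.0, 0.0))
    return (vec[:, top] * gain) * np.sqrt(psi)[:, None]


def _efa_objective(x: np.ndarray, corr: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    psi = np.exp(x)
    d = 1.0 / np.sqrt(psi)
    m = corr * np.outer(d, d)
    theta = np.linalg.eigvalsh(m)
    small = np.sort(theta)[: corr.shape[0] - k]
    small = np.maximum(small, 1e-10)
    f = float(np.sum(small - np.log(small) - 1.0))
    # envelope-theorem gradient: dF/dψ_j = [Σ⁻¹(Σ−R)Σ⁻¹]_jj at the
    # conditionally optimal loadings
    lam = _efa_loadings(corr, psi, k)
    sigma = lam @ lam.T + np.diag(psi)
    inv = np.linalg.inv(sigma)
    omega = inv @ (sigma - corr) @ inv
    grad = np.diag(omega) * psi
    return f, grad


def ml_efa(data_or_corr, k: int, n: int | None = None) -> EFASolution:
    """Unrotated maximum-likelihood exploratory factor analysis.

    Returns the canonical (unrotated) solution with chi² = (n−1)·F_ML and
    df = ((p−k)² − p − k)/2.  Uniquenesses hitting the 0.005 floor are
    flagged as Heywood cases.
    """
    corr, n, names = _as_corr(data_or_corr, n)
    p = corr.shape[0]
    if k < 1:
        raise ValueError("k must be at least 1")
    if p <= k:
        raise ValueError("more variables than factors are required")
    df = ((p - k) ** 2 - p - k) // 2
    if df < 0:
        raise ValueError(f"model with p={p}, k={k} has negative degrees of freedom")

    inv_diag = np.diag(np.linalg.inv(corr))
    start = np.clip(1.0 / inv_diag, 0.05, 0.95)  # 1 − SMC
    bounds = [(np.log(UNIQUENESS_FLOOR), 0.0)] * p
    best = None
    for attempt, x0 in enumerate([np.log(start), np.log(np.full(p, 0.5))]):
        res = optimize.minimize(
            _efa_objective,
            x0,
            args=(corr, k),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and attempt == 0:
            break
    psi = np.exp(best.x)
    lam = _efa_loadings(corr, psi, k)
    heywood = bool(np.any(psi <= UNIQUENESS_FLOOR * 1.0001))
    psi = np.maximum(psi, UNIQUENESS_FLOOR)
    chi2 = max(float((n - 1) * best.fun), 0.0)
    chi2_b, df_b = _baseline_chi2(corr, n)
    residual = corr - (lam @ lam.T + np.diag(psi))
    np.fill_diagonal(residual, 0.0)
    fit = fit_indices(chi2, df, chi2_b, df_b, n, residual)
    return EFASolution(
        k=k,
        loadings=lam,
        factor_corr=np.eye(k),
        uniquenesses=psi,
        fit=fit,
        converged=bool(best.success),
        heywood=heywood,
        variable_names=names,
    )


# ---------------------------------------------------------------------------
# geomin rotation (oblique gradient projection)
# ---------------------------------------------------------------------------

def _geomin_q(lam: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    k = lam.shape[1]
    l2 = lam * lam + eps
    pro = np.exp(np.log(l2).sum(axis=1) / k)
    q = float(pro.sum())
    gq = (2.0 / k) * (lam / l2) * pro[:, None]
    return q, gq


def _gpa_oblique(
    a: np.ndarray, t0: np.ndarray, eps: float, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient-projection minimization of the geomin criterion over oblique
    rotations; returns (pattern, T, criterion, converged)."""
    t = t0.copy()
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = _geomin_q(lam, eps)
    g = -(lam.T @ gq @ ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        gp = g - t * (t * g).sum(axis=0)
        s = np.sqrt((gp * gp).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            v = 1.0 / np.sqrt((x * x).sum(axis=0))
            tt = x * v
            ti = np.linalg.inv(tt)
            lam = a @ ti.T
            ft, gq = _geomin_q(lam, eps)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        t = tt
        f = ft
        g = -(lam.T @ gq @ ti).T
    return lam, t, f, converged


def _sign_align(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip column signs so each column's largest-|λ| entry is positive."""
    signs = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(lam.shape[1])])
    signs[signs == 0] = 1.0
    lam = lam * signs
    phi = phi * np.outer(signs, signs)
    return lam, phi


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading columns."""
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


def align_to_reference(
    lam: np.ndarray, phi: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Permute and sign-flip columns to best match a reference pattern,
    maximizing total |Tucker congruence| via optimal assignment."""
    k = lam.shape[1]
    cong = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cong[i, j] = tucker_congruence(reference[:, i], lam[:, j])
    rows, cols = optimize.linear_sum_assignment(-np.abs(cong))
    perm = cols[np.argsort(rows)]
    lam = lam[:, perm]
    phi = phi[np.ix_(perm, perm)]
    signs = np.sign(np.array([cong[i, perm[i]] for i in range(k)]))
    signs[signs == 0] = 1.0
    lam = lam * signs
    phi = phi * np.outer(signs, signs)
    return lam, phi


def geomin_rotate(
    unrotated: EFASolution,
    epsilon: float = 0.01,
    n_starts: int = 10,
    seed: int = 0,
    reference: np.ndarray | None = None,
) -> EFASolution:
    """Oblique geomin rotation with random starts, keeping the best.

    Single-factor solutions are returned unchanged.  Columns are sign-aligned
    (largest-|loading| entry positive); when ``reference`` is given, columns
    are additionally permuted/flipped to maximize total Tucker congruence.
    Fit indices carry over: rotation leaves the fitted common part, and hence
    every fit statistic, unchanged.
    """
    if unrotated.k == 1:
        lam = unrotated.loadings.copy()
        sign = np.sign(lam[np.abs(lam[:, 0]).argmax(), 0]) or 1.0
        return replace(unrotated, loadings=lam * sign, factor_corr=np.eye(1))
    rng = np.random.default_rng(seed)
    a = unrotated.loadings
    k = unrotated.k
    best: tuple | None = None
    any_converged = False
    for start in range(n_starts):
        if start == 0:
            t0 = np.eye(k)
        else:
            x = rng.standard_normal((k, k))
            t0 = x / np.sqrt((x * x).sum(axis=0))
        lam, t, f, conv = _gpa_oblique(a, t0, epsilon)
        any_converged = any_converged or conv
        if best is None or f < best[2]:
            best = (lam, t, f)
    lam, t, _ = best
    phi = t.T @ t
    lam, phi = _sign_align(lam, phi)
    if reference is not None:
        lam, phi = align_to_reference(lam, phi, reference)
    return replace(
        unrotated,
        loadings=lam,
        factor_corr=phi,
        converged=unrotated.converged and any_converged,
    )


# ---------------------------------------------------------------------------
# factor-count methods
# ---------------------------------------------------------------------------

def parallel_analysis(
    data: Dataset,
    n_reps: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Number of correlation eigenvalues exceeding the random-data percentile.

    Compares each observed eigenvalue with the chosen percentile of the
    corresponding ordered eigenvalue from ``n_reps`` standard-normal datasets
    of identical shape; the count is floored at 1.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be at least 50")
    rng = np.random.default_rng(seed)
    n, p = data.n, data.p
    obs = np.sort(np.linalg.eigvalsh(data.corr()))[::-1]
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        x = rng.standard_normal((n, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    threshold = np.percentile(sims, percentile, axis=0)
    k = int(np.sum(obs > threshold))
    return max(k, 1)


def _ebic(prec: np.ndarray, emp_cov: np.ndarray, n: int, gamma: float) -> float:
    p = prec.shape[0]
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - np.trace(emp_cov @ prec))
    edges = int(np.count_nonzero(np.triu(prec, 1)))
    return -2.0 * loglik + edges * np.log(n) + 4.0 * edges * gamma * np.log(p)


def ega_factor_count(data: Dataset, gamma: float = 0.5, seed: int = 0) -> int:
    """Factor count from a regularized partial-correlation network.

    Fits graphical-lasso precision matrices over a 100-point penalty path,
    picks the extended-BIC-optimal penalty, builds a weighted graph from
    absolute partial correlations, and counts Walktrap communities.  An empty
    network yields k = 1 with a warning.
    """
    from sklearn.covariance import graphical_lasso

    import igraph as ig

    if data.p < 3:
        raise ValueError("at least 3 variables are required")
    emp = data.corr()
    alpha_max = float(np.max(np.abs(emp - np.diag(np.diag(emp)))))
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 0.01), 100)
    best_prec, best_score = None, np.inf
    for alpha in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(emp, alpha=alpha, max_iter=200)
        except (FloatingPointError, ValueError):
            continue
        score = _ebic(prec, emp, data.n, gamma)
        if score < best_score:
            best_score, best_prec = score, prec
    if best_prec is None:
        warnings.warn("graphical lasso failed along the whole path; k = 1")
        return 1
    d = np.sqrt(np.diag(best_prec))
    pc = -best_prec / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    weights = np.abs(pc)
    weights[weights < 1e-8] = 0.0
    if not np.any(weights):
        warnings.warn("estimated network has no edges; k = 1")
        return 1
    graph = ig.Graph.Weighted_Adjacency(
        weights.tolist(), mode="undirected", attr="weight", loops=False
    )
    communities = graph.community_walktrap(
        weights=graph.es["weight"], steps=4
    ).as_clustering()
    return max(len(communities), 1)


# ---------------------------------------------------------------------------
# confirmatory factor analysis (congeneric)
# ---------------------------------------------------------------------------

def _cfa_unpack(x, q, k, factor_idx):
    lam_val = x[:q]
    psi = np.exp(x[q : 2 * q])
    t = np.eye(k)
    pos = 2 * q
    for j in range(1, k):
        row = x[pos : pos + j + 1]
        pos += j + 1
        t[j, : j + 1] = row / np.linalg.norm(row)
        t[j, j + 1 :] = 0.0
    phi = t @ t.T
    lam = np.zeros((q, k))
    lam[np.arange(q), factor_idx] = lam_val
    return lam, phi, psi


def _cfa_discrepancy(sigma, s):
    sign, logdet_s = np.linalg.slogdet(s)
    sign2, logdet = np.linalg.slogdet(sigma)
    if sign2 <= 0:
        return np.inf, None
    inv = np.linalg.inv(sigma)
    f = logdet + np.trace(s @ inv) - logdet_s - s.shape[0]
    return float(f), inv


def cfa_fit(
    data: Dataset,
    structure: dict[str, str],
    allow_corr_factors: bool = True,
    n: int | None = None,
    corr: np.ndarray | None = None,
) -> CFAResult:
    """Congeneric CFA by ML on the sample correlation matrix.

    ``structure`` maps each variable to its factor; cross-loadings are fixed
    to zero and residuals are independent.  Factor variances are fixed at 1
    with all loadings free; factor correlations are free when
    ``allow_corr_factors``.  An explicit (corr, n) pair may replace the data.
    """
    variables = [v for v in (data.variable_names if data is not None else structure) if v in structure]
    factors = sorted(set(structure.values()), key=lambda f: list(structure.values()).index(f))
    q, k = len(variables), len(factors)
    if q < 3:
        raise ValueError("at least 3 variables are required")
    counts = {f: sum(1 for v in variables if structure[v] == f) for f in factors}
    thin = [f for f, c in counts.items() if c < (3 if k == 1 else 2)]
    if thin:
        raise ValueError(f"under-identified factors (too few indicators): {counts}")
    if data is not None:
        sub = data.subset(variables)
        s, n = sub.corr(), sub.n
    else:
        s = np.asarray(corr, dtype=float)
        if n is None:
            raise ValueError("n must be supplied with a correlation matrix")
    factor_idx = np.array([factors.index(structure[v]) for v in variables])

    # start values: loadings from mean within-factor correlation
    lam0 = np.empty(q)
    for j, f in enumerate(factors):
        idx = np.flatnonzero(factor_idx == j)
        if len(idx) > 1:
            block = s[np.ix_(idx, idx)]
            r_bar = float(np.abs(block[np.triu_indices(len(idx), 1)]).mean())
        else:
            r_bar = 0.25
        lam0[idx] = np.sqrt(np.clip(r_bar, 0.04, 0.81))
    psi0 = np.clip(1.0 - lam0**2, 0.05, 0.95)
    phi_params0 = []
    for j in range(1, k):
        row = np.zeros(j + 1)
        row[j] = 1.0
        phi_params0.extend(row)
    x0 = np.concatenate([lam0, np.log(psi0), np.array(phi_params0)])
    n_phi = len(phi_params0)

    def objective(x):
        lam, phi, psi = _cfa_unpack(x, q, k, factor_idx)
        if not allow_corr_factors:
            phi = np.eye(k)
        sigma = lam @ phi @ lam.T + np.diag(psi)
        f, inv = _cfa_discrepancy(sigma, s)
        if not np.isfinite(f):
            return 1e6, np.zeros_like(x)
        omega = inv @ (sigma - s) @ inv
        grad = np.empty_like(x)
        grad[:q] = 2.0 * (omega @ lam @ phi)[np.arange(q), factor_idx]
        grad[q : 2 * q] = np.diag(omega) * psi
        # few Φ parameters: central finite differences
        h = 1e-6
        for i in range(n_phi):
            xp = x.copy()
            xp[2 * q + i] += h
            lam_p, phi_p, psi_p = _cfa_unpack(xp, q, k, factor_idx)
            if not allow_corr_factors:
                phi_p = np.eye(k)
            fp, _ = _cfa_discrepancy(lam_p @ phi_p @ lam_p.T + np.diag(psi_p), s)
            xm = x.copy()
            xm[2 * q + i] -= h
            lam_m, phi_m, psi_m = _cfa_unpack(xm, q, k, factor_idx)
            if not allow_corr_factors:
                phi_m = np.eye(k)
            fm, _ = _cfa_discrepancy(lam_m @ phi_m @ lam_m.T + np.diag(psi_m), s)
            grad[2 * q + i] = (fp - fm) / (2 * h)
        return f, grad

    bounds = (
        [(-2.0, 2.0)] * q
        + [(np.log(UNIQUENESS_FLOOR), np.log(2.0))] * q
        + [(-10.0, 10.0)] * n_phi
    )
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-9},
    )
    lam, phi, psi = _cfa_unpack(res.x, q, k, factor_idx)
    if not allow_corr_factors:
        phi = np.eye(k)
    # sign convention: majority-positive loadings per factor
    for j in range(k):
        idx = np.flatnonzero(factor_idx == j)
        if lam[idx, j].sum() < 0:
            lam[idx, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
            np.fill_diagonal(phi, 1.0)
    sigma = lam @ phi @ lam.T + np.diag(psi)
    n_free = 2 * q + (k * (k - 1) // 2 if allow_corr_factors else 0)
    df = q * (q + 1) // 2 - n_free
    chi2 = max(float((n - 1) * res.fun), 0.0)
    chi2_b, df_b = _baseline_chi2(s, n)
    d = np.sqrt(np.diag(sigma))
    residual = s - sigma
    residual = residual / np.outer(d, d)
    fit = fit_indices(chi2, df, chi2_b, df_b, n, residual)
    lam_flat = lam[np.arange(q), factor_idx]
    return CFAResult(
        loadings={v: float(lam_flat[i]) for i, v in enumerate(variables)},
        factor_of={v: structure[v] for v in variables},
        factor_corr=phi,
        factor_names=factors,
        residuals={v: float(psi[i]) for i, v in enumerate(variables)},
        fit=fit,
        converged=bool(res.success),
    )
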