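"""Exploratory factor analysis primitives.

Three pieces, kept deliberately separate:

* principal axis factoring (PAF): iterated eigendecomposition of the reduced
  correlation matrix, communalities initialised at squared multiple
  correlations;
* Geomin oblique rotation via the gradient-projection algorithm, with
  multiple seeded random starts (the Geomin criterion has local minima);
* maximum-likelihood factor extraction by profile minimisation over
  uniquenesses, used solely to evaluate the ML discrepancy and the fit
  indices (chi-square with Bartlett's correction, CFI, TLI, RMSEA).

Reported loadings come from PAF + Geomin; fit indices come from a parallel ML
fit at the same number of factors.  This mirrors common applied practice
where the pattern matrix and the fit assessment are produced by different
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ConvergenceError",
    "FitIndices",
    "principal_axis_factoring",
    "geomin_rotate",
    "ml_discrepancy",
    "ml_fit_indices",
    "tucker_congruence",
]


class ConvergenceError(RuntimeError):
    """An iterative factor routine failed to converge."""

    def __init__(self, message: str, iterations: int):
        super().__init__(f"{message} (after {iterations} iterations)")
        self.iterations = iterations


@dataclass(frozen=True)
class FitIndices:
    """ML-based global fit of a factor model."""

    chi_square: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each variable on the rest."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def principal_axis_factoring(
    R: np.ndarray,
    n_factors: int,
    *,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated PAF loadings of a correlation matrix.

    Returns ``(loadings, eigenvalues)`` where ``eigenvalues`` are those of the
    original correlation matrix (used for the eigenvalue >= 1 retention rule).

    Raises
    ------
    ConvergenceError
        If communalities do not stabilise.
    numpy.linalg.LinAlgError
        If the correlation matrix is singular.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("need 1 <= n_factors < number of variables")
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]

    h2 = _smc(R)
    h2 = np.clip(h2, 1e-4, 1 - 1e-4)
    loadings = None
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order[:n_factors]], vecs[:, order[:n_factors]]
        vals = np.clip(vals, 1e-10, None)
        loadings = vecs * np.sqrt(vals)
        h2_new = np.clip(np.sum(loadings**2, axis=1), 1e-6, 1 - 1e-6)
        # mild damping guards against oscillation when over-extracting
        h2_new = 0.9 * h2_new + 0.1 * h2
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    else:
        raise ConvergenceError("principal axis factoring did not converge", max_iter)

    # sign convention: each column's loading sum is non-negative
    signs = np.where(loadings.sum(axis=0) < 0, -1.0, 1.0)
    return loadings * signs, eigenvalues


def _geomin_criterion(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Geomin criterion and its gradient with respect to the loadings."""
    L2 = L**2 + eps
    m = L.shape[1]
    gmean = np.exp(np.log(L2).sum(axis=1) / m)
    f = float(gmean.sum())
    G = (2.0 / m) * (L / L2) * gmean[:, None]
    return f, G


def _gpa_oblique(
    A: np.ndarray,
    T0: np.ndarray,
    eps: float,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient-projection minimisation of the Geomin criterion, oblique case.

    ``A`` is the unrotated loading matrix; the rotated pattern is
    ``L = A @ inv(T).T`` with T constrained to unit-length columns.
    Returns (pattern, factor correlation Phi, criterion value, converged).
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_criterion(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)  # project onto the constraint manifold
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gqt = _geomin_criterion(Lt, eps)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Xi, Lt, ft, Gqt
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def _random_orthonormal(k: int, rng: np.random.Generator) -> np.ndarray:
    M = rng.standard_normal((k, k))
    Q, _ = np.linalg.qr(M)
    return Q


def geomin_rotate(
    loadings: np.ndarray,
    *,
    eps: float = 0.01,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Obliquely rotate a loading matrix by the Geomin criterion.

    Runs the gradient-projection algorithm from the identity start plus
    ``n_starts`` seeded random orthonormal starts and keeps the solution with
    the lowest criterion value.  Columns are reordered by descending sum of
    squared loadings and sign-aligned so the dominant loading of each factor
    is positive.

    Returns ``(pattern, phi)`` -- the rotated pattern matrix and the factor
    correlation matrix.
    """
    A = np.asarray(loadings, dtype=float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    rng = np.random.default_rng(seed)
    starts = [np.eye(k)] + [_random_orthonormal(k, rng) for _ in range(n_starts)]
    best = None
    for T0 in starts:
        L, Phi, f, ok = _gpa_oblique(A, T0, eps)
        if ok and (best is None or f < best[2]):
            best = (L, Phi, f)
    if best is None:
        raise ConvergenceError("Geomin rotation failed from every start", 1000)
    L, Phi, _ = best

    order = np.argsort(-np.sum(L**2, axis=0))
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    dom = np.abs(L).argmax(axis=0)
    signs = np.where(L[dom, np.arange(k)] < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


def ml_discrepancy(R: np.ndarray, n_factors: int) -> float:
    """Minimised ML discrepancy of a ``n_factors`` model for correlation R.

    Profile method: for fixed uniquenesses psi the optimal loadings are known
    in closed form, leaving the objective

        F(psi) = sum_{j>k} (theta_j - log theta_j - 1)

    over the trailing eigenvalues theta of psi^{-1/2} R psi^{-1/2}, minimised
    here over log-uniquenesses with L-BFGS-B from several starts.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    k = n_factors

    def objective(logpsi: np.ndarray) -> float:
        psi = np.exp(logpsi)
        scale = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(scale, scale)
        theta = np.sort(np.linalg.eigvalsh(Rs))[::-1]
        tail = np.clip(theta[k:], 1e-12, None)
        return float(np.sum(tail - np.log(tail) - 1.0))

    smc = np.clip(_smc(R), 0.05, 0.95)
    starts = [np.log(1.0 - smc), np.log(np.full(p, 0.5))]
    best = np.inf
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(1e-4), np.log(1.0))] * p,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def ml_fit_indices(R: np.ndarray, n_factors: int, n_obs: int) -> FitIndices:
    """Chi-square (Bartlett-corrected), CFI, TLI and RMSEA of a factor model."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    k = n_factors
    df = ((p - k) ** 2 - (p + k)) // 2
    if df <= 0:
        raise ValueError(f"{k} factors on {p} variables leaves no degrees of freedom")
    F = ml_discrepancy(R, k)
    correction = n_obs - 1 - (2 * p + 5) / 6 - 2 * k / 3
    chi2 = max(correction * F, 0.0)
    pval = float(stats.chi2.sf(chi2, df))

    # independence (null) model
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is not positive definite")
    F0 = -logdet
    df0 = p * (p - 1) // 2
    chi2_0 = max((n_obs - 1 - (2 * p + 5) / 6) * F0, 0.0)

    d = max(chi2 - df, 0.0)
    d0 = max(chi2_0 - df0, d)
    cfi = 1.0 - d / d0 if d0 > 0 else 1.0
    denom = chi2_0 / df0 - 1.0
    tli = (chi2_0 / df0 - chi2 / df) / denom if denom > 0 else 1.0
    rmsea = float(np.sqrt(max(chi2 / df - 1.0, 0.0) / (n_obs - 1)))
    # TLI may exceed 1 in small samples; reported as computed
    return FitIndices(chi_square=chi2, df=df, p=pval, cfi=cfi, tli=tli, rmsea=rmsea)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Mean Tucker congruence between two loading matrices.

    Factors of ``B`` are greedily matched to factors of ``A`` by absolute
    congruence (sign-invariant); returns the mean matched coefficient.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have equal shape")
    k = A.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            denom = np.sqrt(np.sum(A[:, i] ** 2) * np.sum(B[:, j] ** 2))
            C[i, j] = np.abs(np.sum(A[:, i] * B[:, j])) / denom if denom > 0 else 0.0
    remaining = set(range(k))
    total = 0.0
    for i in range(k):
        j = max(remaining, key=lambda j: C[i, j])
        total += C[i, j]
        remaining.remove(j)
    return total / k
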