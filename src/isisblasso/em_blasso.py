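"""EM estimation of the Bayesian LASSO for the screened SNP set.

Model: y = X b + sum_k Z_k g_k + e, with g_k ~ N(0, s2_k) per SNP,
e ~ N(0, s2 I).  Each SNP contributes one column (fully homozygous
biallelic data), so g_k is scalar.  Treating the g_k as missing data, the
E-step takes their posterior moments under the current variance components
and the M-step updates (b, s2, s2_k).  A per-SNP variance that collapses
to zero removes that SNP from the model permanently — this is the
LASSO-like sparsity that filters the screened set down to real signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "VOperator",
    "EMBlassoFit",
    "build_V",
    "gls_beta",
    "e_step",
    "update_sigma_k",
    "update_residual_variance",
    "fit_em_blasso",
]

# per-SNP variances below this are treated as exactly zero (absorbing)
ABSORB_TOL = 1e-9


class VOperator:
    """The marginal covariance V = sum_k Z_k Z_k' s2_k + I s2.

    Exposes solves and the log-determinant through one dense Cholesky
    factorization (n is a few hundred at the scale this package targets).
    """

    def __init__(self, Z: np.ndarray, sigma_k2: np.ndarray, sigma2: float):
        if sigma2 <= 0:
            raise ValueError("residual variance sigma2 must be positive")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.ndim != 2:
            raise ValueError("Z must be 2-D (n x tau)")
        sigma_k2 = np.asarray(sigma_k2, dtype=float).ravel()
        if sigma_k2.size != Z.shape[1]:
            raise ValueError("one variance component per Z column required")
        if np.any(sigma_k2 < 0):
            raise ValueError("variance components must be non-negative")
        n = Z.shape[0]
        self.sigma2 = float(sigma2)
        self.matrix = Z @ (Z * sigma_k2).T + np.eye(n) * sigma2
        self._chol = linalg.cho_factor(self.matrix, lower=True)

    def solve(self, b: np.ndarray) -> np.ndarray:
        """V^{-1} b for a vector or matrix right-hand side."""
        return linalg.cho_solve(self._chol, np.asarray(b, dtype=float))

    @property
    def logdet(self) -> float:
        c = self._chol[0]
        return float(2.0 * np.log(np.diag(c)).sum())


def build_V(Z: np.ndarray, sigma_k2: np.ndarray, sigma2: float) -> VOperator:
    """Construct the covariance operator for the current parameters."""
    return VOperator(Z, sigma_k2, sigma2)


def gls_beta(X: np.ndarray, V: VOperator, y: np.ndarray) -> np.ndarray:
    """Generalized least squares: (X'V^-1 X)^-1 X'V^-1 y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    ViX = V.solve(X)
    A = X.T @ ViX
    b = ViX.T @ y
    return np.linalg.solve(A, b)


def e_step(
    Z_k: np.ndarray,
    V: VOperator,
    X: np.ndarray,
    beta: np.ndarray,
    y: np.ndarray,
    sigma_k2: float,
) -> tuple[float, float, float]:
    """Posterior moments of one SNP effect: (E[g], E[g^2], var[g]).

    E[g] = s2_k Z_k'V^-1 (y - Xb);  var[g] = s2_k - s2_k Z_k'V^-1 Z_k s2_k.
    A collapsed SNP (s2_k = 0) has all three moments zero.
    """
    if sigma_k2 == 0:
        return 0.0, 0.0, 0.0
    Z_k = np.asarray(Z_k, dtype=float).ravel()
    resid = np.asarray(y, float).ravel() - np.atleast_2d(X) @ np.asarray(beta, float)
    ViZ = V.solve(Z_k)
    e_g = float(sigma_k2 * (Z_k @ V.solve(resid)))
    var_g = float(sigma_k2 - sigma_k2 * (Z_k @ ViZ) * sigma_k2)
    if var_g < -1e-10:
        raise FloatingPointError(f"negative posterior variance {var_g}")
    var_g = max(var_g, 0.0)
    return e_g, e_g**2 + var_g, var_g


def update_sigma_k(
    E_gamma_sq_k: float,
    prior: str = "flat",
    tau0: float = -2.0,
    omega0: float = 0.0,
) -> float:
    """M-step for a per-SNP variance component.

    ``flat``: s2_k = E[g'g].  ``inv_chi2`` (scaled inverse chi-square with
    hyperparameters (tau0, omega0)): s2_k = (E[g'g] + omega0)/(1 + tau0 + 2);
    the degenerate choice (tau0, omega0) = (-2, 0) recovers the flat update.
    """
    if E_gamma_sq_k < 0:
        raise ValueError("E[gamma'gamma] must be non-negative")
    if prior == "flat":
        return float(E_gamma_sq_k)
    if prior == "inv_chi2":
        denom = 1.0 + tau0 + 2.0
        if denom <= 0:
            raise ValueError("prior hyperparameters give non-positive denominator")
        return float((E_gamma_sq_k + omega0) / denom)
    raise ValueError(f"unknown prior {prior!r}")


def update_residual_variance(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    Z: np.ndarray,
    E_gamma: np.ndarray,
) -> float:
    """Residual-variance M-step:
    s2 = (1/n) (y - Xb)' [ (y - Xb) - sum_k Z_k E(g_k) ]."""
    y = np.asarray(y, float).ravel()
    r = y - np.atleast_2d(X) @ np.asarray(beta, float)
    adj = r - np.atleast_2d(Z) @ np.asarray(E_gamma, float) if np.size(Z) else r
    s2 = float(r @ adj) / y.size
    if s2 <= 0:
        raise FloatingPointError(
            f"non-positive residual variance estimate {s2}; model degenerate"
        )
    return s2


@dataclass
class EMBlassoFit:
    """Converged (or best-effort) state of the EM run."""

    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    sigma_k2: np.ndarray
    sigma2: float
    var_gamma: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    snp_indices: np.ndarray | None = field(default=None)  # bookkeeping for callers

    @property
    def support(self) -> np.ndarray:
        """Positions (within the submitted Z block) of surviving SNPs."""
        return np.where(self.gamma_hat != 0)[0]


def _loglik(V: VOperator, X: np.ndarray, beta: np.ndarray, y: np.ndarray) -> float:
    r = y - X @ beta
    n = y.size
    return float(-0.5 * (n * np.log(2 * np.pi) + V.logdet + r @ V.solve(r)))


def fit_em_blasso(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    prior: str = "inv_chi2",
    prior_params: tuple[float, float] = (0.0, 0.0),
) -> EMBlassoFit:
    """Run the EM cycle to convergence.

    ``y`` is the original (uncorrected) phenotype; ``X`` holds the overall
    mean column and any structure covariates; ``Z`` holds the tau screened
    SNP columns.  Convergence: max relative parameter change below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        Z = Z.reshape(y.size, 0)
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D")
    if np.isnan(X).any() or np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("NaN in EM-BLASSO inputs")
    n, tau = Z.shape

    # initialization: unit per-SNP variances; residual variance from the
    # OLS fit of y on the fixed effects alone
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta
    sigma2 = float(resid0 @ resid0 / max(n - X.shape[1], 1))
    sigma2 = max(sigma2, 1e-12)
    sigma_k2 = np.ones(tau)
    e_g = np.zeros(tau)
    var_g = np.zeros(tau)

    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        active = np.where(sigma_k2 > 0)[0]
        Za = Z[:, active]
        V = build_V(Za, sigma_k2[active], sigma2)
        beta_new = gls_beta(X, V, y)
        loglik_trace.append(_loglik(V, X, beta_new, y))

        resid = y - X @ beta_new
        Vr = V.solve(resid)
        ViZ = V.solve(Za) if active.size else np.empty((n, 0))
        e_g_new = np.zeros(tau)
        var_new = np.zeros(tau)
        e_gsq = np.zeros(tau)
        if active.size:
            s2a = sigma_k2[active]
            e_g_new[active] = s2a * (Za.T @ Vr)
            quad = np.einsum("ij,ij->j", Za, ViZ)
            v = s2a - s2a * quad * s2a
            if np.any(v < -1e-10):
                raise FloatingPointError("negative posterior variance in E-step")
            var_new[active] = np.clip(v, 0.0, None)
            e_gsq[active] = e_g_new[active] ** 2 + var_new[active]

        sigma_k2_new = np.array(
            [update_sigma_k(g2, prior, *prior_params) for g2 in e_gsq]
        )
        sigma_k2_new[sigma_k2_new < ABSORB_TOL] = 0.0
        sigma2_new = update_residual_variance(y, X, beta_new, Z, e_g_new)

        old = np.concatenate([beta, sigma_k2, [sigma2]])
        new = np.concatenate([beta_new, sigma_k2_new, [sigma2_new]])
        delta = np.max(np.abs(new - old) / (np.abs(old) + 1e-10))
        beta, sigma_k2, sigma2 = beta_new, sigma_k2_new, sigma2_new
        e_g, var_g = e_g_new, var_new
        if np.isnan(new).any():
            raise FloatingPointError("NaN encountered during EM iteration")
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM-BLASSO did not converge in {max_iter} iterations", RuntimeWarning
        )

    # zero variance implies zero posterior
    e_g[sigma_k2 == 0] = 0.0
    var_g[sigma_k2 == 0] = 0.0
    return EMBlassoFit(
        beta_hat=beta,
        gamma_hat=e_g,
        sigma_k2=sigma_k2,
        sigma2=sigma2,
        var_gamma=var_g,
        loglik_trace=np.array(loglik_trace),
        n_iter=it,
        converged=converged,
    )
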