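"""SCAD-penalized least squares by cyclic coordinate descent.

The smoothly clipped absolute deviation penalty is linear near zero (like
the lasso), transitions quadratically, and is constant for large effects,
so large coefficients are left unshrunk (near-unbiasedness) while small
ones are thresholded away.  Inside the screening rounds the fit is used
purely for support selection — final effect estimates come from the
EM-Bayesian-LASSO stage.

The solver minimizes

    f(b) = (1/2n) ||y - X b||^2 + sum_j rho(|b_j|; lambda, gamma)

with columns rescaled internally so x_j'x_j = n, the scaling under which
the scalar coordinate update has the exact closed form used below and
lambda_max = max_j |x_j'y| / n zeroes every coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScadPath",
    "scad_penalty",
    "scad_univariate_update",
    "fit_scad",
    "select_model",
]


def _check_gamma(gamma: float) -> None:
    if gamma <= 2:
        raise ValueError("SCAD concavity parameter gamma must exceed 2")


def scad_penalty(beta: float, lam: float, gamma: float = 3.7) -> float:
    """Evaluate the SCAD penalty rho(|beta|; lam, gamma).

    Three branches: lam*|b| up to |b| = lam, a quadratic blend up to
    gamma*lam, then the constant lam^2 (gamma^2 - 1) / (2 (gamma - 1)).
    Continuous in |beta|.
    """
    _check_gamma(gamma)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    b = abs(float(beta))
    if b <= lam:
        return lam * b
    if b <= gamma * lam:
        return (gamma * lam * b - 0.5 * (b**2 + lam**2)) / (gamma - 1)
    return lam**2 * (gamma**2 - 1) / (2 * (gamma - 1))


def scad_univariate_update(z: float, lam: float, gamma: float = 3.7) -> float:
    """Exact minimizer of (1/2)(z - b)^2 + rho(|b|; lam, gamma).

    Soft-thresholding for |z| <= 2 lam, the blended form for
    2 lam < |z| <= gamma lam, and the identity (no shrinkage) beyond.
    """
    _check_gamma(gamma)
    az = abs(z)
    if az <= 2 * lam:
        return float(np.sign(z) * max(az - lam, 0.0))
    if az <= gamma * lam:
        return float(((gamma - 1) * z - np.sign(z) * gamma * lam) / (gamma - 2))
    return float(z)


@dataclass
class ScadPath:
    """Solutions along a decreasing lambda grid over the submitted columns."""

    lambdas: np.ndarray          # strictly decreasing, lambdas[0] = lambda_max
    gamma: float
    coefficients: np.ndarray     # (n_lambdas, p), original column scale
    intercepts: np.ndarray       # (n_lambdas,)
    rss: np.ndarray              # residual sum of squares per lambda
    selected_lambda: float | None = None
    selected_support: np.ndarray | None = None

    def support(self, i: int) -> np.ndarray:
        return np.where(self.coefficients[i] != 0)[0]


def scad_objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float, gamma: float = 3.7
) -> float:
    """The penalized objective the solver minimizes (internal x'x = n scale)."""
    n = y.size
    r = y - X @ beta
    return float(r @ r / (2 * n) + sum(scad_penalty(b, lam, gamma) for b in beta))


def fit_scad(
    X_sub: np.ndarray,
    y: np.ndarray,
    gamma: float = 3.7,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-4,
    max_sweeps: int = 1000,
    lambdas: np.ndarray | None = None,
) -> ScadPath:
    """Coordinate-descent SCAD path on a moderate-size column block.

    ``X_sub`` should have standardized columns and ``y`` should be
    centered.  The path is warm-started from the all-zero solution at
    lambda_max down a log-spaced grid; convergence at each lambda is a full
    sweep with max absolute coefficient change below ``tol``.
    """
    _check_gamma(gamma)
    X_sub = np.asarray(X_sub, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(X_sub).any() or np.isnan(y).any():
        raise ValueError("NaN in SCAD inputs")
    n, p = X_sub.shape

    # internal rescale to x'x = n (exactness of the scalar update)
    norms = np.sqrt((X_sub**2).sum(axis=0) / n)
    if np.any(norms == 0):
        raise ValueError("zero-variance column submitted to SCAD")
    Xs = X_sub / norms

    if lambdas is None:
        lam_max = np.max(np.abs(Xs.T @ y)) / n
        if lam_max == 0:
            lam_max = 1.0
        lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)
    else:
        lambdas = np.asarray(lambdas, dtype=float)

    coefs = np.zeros((lambdas.size, p))
    rss = np.empty(lambdas.size)
    beta = np.zeros(p)
    r = y.copy()
    for i, lam in enumerate(lambdas):
        for sweep in range(max_sweeps):
            # full cyclic sweep; then iterate the active set until stable
            delta = _sweep(Xs, r, beta, lam, gamma, n, np.arange(p))
            active = np.where(beta != 0)[0]
            for _ in range(max_sweeps):
                d_act = _sweep(Xs, r, beta, lam, gamma, n, active)
                if d_act < tol:
                    break
                active = np.where(beta != 0)[0]
            if delta < tol:
                break
        else:
            warnings.warn(
                f"SCAD coordinate descent did not converge at lambda={lam:.4g}; "
                "keeping last iterate",
                RuntimeWarning,
            )
        coefs[i] = beta / norms  # back to the submitted column scale
        rss[i] = float(r @ r)
    intercepts = np.full(lambdas.size, float(y.mean()))
    return ScadPath(
        lambdas=lambdas, gamma=gamma, coefficients=coefs, intercepts=intercepts, rss=rss
    )


def _sweep(
    Xs: np.ndarray,
    r: np.ndarray,
    beta: np.ndarray,
    lam: float,
    gamma: float,
    n: int,
    order: np.ndarray,
) -> float:
    """One cyclic pass over ``order``; mutates beta and residual in place."""
    max_delta = 0.0
    for j in order:
        bj = beta[j]
        z = Xs[:, j] @ r / n + bj
        bnew = scad_univariate_update(z, lam, gamma)
        if bnew != bj:
            r += Xs[:, j] * (bj - bnew)
            beta[j] = bnew
            max_delta = max(max_delta, abs(bnew - bj))
    return max_delta


def select_model(
    path: ScadPath,
    X_sub: np.ndarray,
    y: np.ndarray,
    criterion: str = "bic",
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Tune lambda on the fitted path and return the winning support.

    BIC (default): n log(RSS/n) + df log(n) with df = support size; ties go
    to the smaller support, then to the larger lambda.  "cv" uses K-fold
    cross-validated squared error on refitted paths.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if criterion == "bic":
        scores = np.empty(path.lambdas.size)
        for i in range(path.lambdas.size):
            rss = max(path.rss[i], 1e-300)
            df = int((path.coefficients[i] != 0).sum())
            scores[i] = n * np.log(rss / n) + df * np.log(n)
    elif criterion == "cv":
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % n_folds
        err = np.zeros(path.lambdas.size)
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            sub = fit_scad(
                X_sub[tr], y[tr] - y[tr].mean(), gamma=path.gamma, lambdas=path.lambdas
            )
            pred = X_sub[te] @ sub.coefficients.T + y[tr].mean()
            err += ((y[te, None] - pred) ** 2).sum(axis=0)
        scores = err / n
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    best = np.min(scores)
    cand = np.where(scores <= best + 1e-12)[0]
    sizes = np.array([(path.coefficients[i] != 0).sum() for i in cand])
    cand = cand[sizes == sizes.min()]
    i_star = int(cand.min())  # largest lambda among remaining ties
    path.selected_lambda = float(path.lambdas[i_star])
    path.selected_support = path.support(i_star)
    return path.selected_support
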