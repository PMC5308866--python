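"""Stage 1 of the algorithm: correlation-learning (sure independence)
screening with a significance criterion, iterated once on residuals.

The screen keeps every SNP whose marginal Pearson correlation with the
(fixed-effect-corrected) phenotype is two-sided significant at level
``alpha`` under the exact Student-t test, t = r sqrt((n-2)/(1-r^2)) with
n-2 degrees of freedom — no multiple-testing correction, by design: the
screen is deliberately liberal and the downstream shrinkage removes the
false entries.  SCAD selection inside each round reduces the screened set
to the round's survivors; round 2 repeats the screen on the residuals of
the phenotype regressed on round-1 survivors, so SNPs that are marginally
uncorrelated with the trait but associated conditionally can be recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeData, PhenotypeVector, StructureMatrix
from .scad import fit_scad, select_model

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "correct_fixed_effects",
    "standardize_columns",
    "critical_correlation",
    "marginal_screen",
    "iterative_screen",
]


@dataclass
class ScreeningResult:
    """Index sets produced by the two screening rounds (0-based indices)."""

    K1: np.ndarray
    T1: np.ndarray
    T2: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.K1 = np.asarray(self.K1, dtype=int)
        self.T1 = np.asarray(self.T1, dtype=int)
        self.T2 = np.asarray(self.T2, dtype=int)
        if not np.isin(self.T1, self.K1).all():
            raise ValueError("T1 must be a subset of K1")
        if np.intersect1d(self.T1, self.T2).size:
            raise ValueError("T1 and T2 must be disjoint")

    @property
    def tau1(self) -> int:
        return self.T1.size

    @property
    def tau2(self) -> int:
        return self.T2.size

    @property
    def union(self) -> np.ndarray:
        """T1 ∪ T2, sorted; size tau1 + tau2."""
        return np.sort(np.concatenate([self.T1, self.T2]))


def correct_fixed_effects(y: PhenotypeVector, Q: StructureMatrix) -> PhenotypeVector:
    """Remove fixed effects by OLS: returns y - Q @ alpha_hat.

    With an intercept-only Q this is mean-centering.  The corrected trait is
    the working response for screening only; final estimation uses the
    original phenotype.
    """
    yv = y.values
    Qm = Q.columns
    n, q = Qm.shape
    if n != yv.size:
        raise ValueError("phenotype and structure matrix row counts differ")
    if q >= n:
        raise ValueError("structure matrix leaves no residual degrees of freedom")
    alpha, _, rank, _ = np.linalg.lstsq(Qm, yv, rcond=None)
    if rank < q:
        raise ValueError("structure matrix is rank deficient")
    return PhenotypeVector(yv - Qm @ alpha)


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center each column to mean 0 and scale to sample sd 1 (n-1 denominator)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.where(sd == 0)[0][0])
        raise ValueError(f"column {j} has zero variance; exclude monomorphic columns")
    return (X - X.mean(axis=0)) / sd


def critical_correlation(n: int, alpha: float) -> float:
    """Smallest |r| that is two-sided significant at level ``alpha``.

    Inverts the exact test: t* = t_{1-alpha/2, n-2}, r* = t*/sqrt(t*^2 + n-2).
    """
    if n < 4:
        raise ValueError("need n >= 4 for the correlation test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_star / np.sqrt(t_star**2 + (n - 2)))


def marginal_screen(
    X_std: np.ndarray, y: np.ndarray | PhenotypeVector, alpha: float = 0.01
) -> np.ndarray:
    """Component-wise correlation screen: indices significant at ``alpha``.

    With standardized columns the marginal regression coefficients
    r = X'y are proportional to the sample correlations, so the screen
    thresholds |corr(x_j, y)| at :func:`critical_correlation`; ties at the
    threshold are kept.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    n = yv.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    yc = yv - yv.mean()
    sy = yc.std(ddof=1)
    if sy == 0:
        return np.array([], dtype=int)
    # X_std has mean-0, sd-1 columns => corr_j = x_j'yc / ((n-1) sd(y))
    corr = X_std.T @ yc / ((n - 1) * sy)
    r_star = critical_correlation(n, alpha)
    return np.where(np.abs(corr) >= r_star)[0]


def _ols_residuals(y: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Residuals of y on [1 | cols]."""
    design = np.column_stack([np.ones(y.size), cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def iterative_screen(
    X: GenotypeData | np.ndarray,
    y_c: PhenotypeVector,
    alpha: float = 0.01,
    n_rounds: int = 2,
    scad_gamma: float = 3.7,
    scad_criterion: str = "bic",
    n_lambdas: int = 100,
) -> ScreeningResult:
    """Run the screening stage: (screen -> SCAD) once, then once more on
    residuals restricted to the not-yet-selected SNPs.

    ``X`` may be a :class:`GenotypeData` (monomorphic columns are excluded
    automatically) or a plain matrix.  Deterministic: no internal randomness.
    """
    if isinstance(X, GenotypeData):
        mat = X.matrix
        eligible = ~X.monomorphic
    else:
        mat = np.asarray(X, dtype=float)
        eligible = mat.std(axis=0, ddof=1) > 0
    p = mat.shape[1]
    elig_idx = np.where(eligible)[0]
    X_std = np.empty_like(mat)
    X_std[:, elig_idx] = standardize_columns(mat[:, elig_idx])

    yv = y_c.values
    selected: list[np.ndarray] = []
    K1_global = np.array([], dtype=int)
    response = yv
    remaining = elig_idx
    for rnd in range(n_rounds):
        resp_sd = response.std(ddof=1)
        if resp_sd == 0:
            break
        resp_std = (response - response.mean()) / resp_sd
        k_local = marginal_screen(X_std[:, remaining], resp_std, alpha=alpha)
        K = remaining[k_local]
        if rnd == 0:
            K1_global = K
        if K.size == 0:
            if rnd == 0:
                logger.warning("marginal screen retained no SNPs; empty result")
            break
        path = fit_scad(
            X_std[:, K], resp_std, gamma=scad_gamma, n_lambdas=n_lambdas
        )
        support_local = select_model(path, X_std[:, K], resp_std, criterion=scad_criterion)
        T = K[np.asarray(sorted(support_local), dtype=int)]
        selected.append(T)
        if T.size == 0:
            break
        all_sel = np.concatenate(selected)
        remaining = np.setdiff1d(remaining, all_sel)
        response = _ols_residuals(yv, mat[:, all_sel])
        logger.info("screen round %d: |K|=%d, selected %d", rnd + 1, K.size, T.size)

    T1 = selected[0] if selected else np.array([], dtype=int)
    T2 = (
        np.concatenate(selected[1:])
        if len(selected) > 1
        else np.array([], dtype=int)
    )
    return ScreeningResult(K1=K1_global, T1=np.sort(T1), T2=np.sort(T2))
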