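"""Performance metrics for the simulation experiments.

A call counts as a detection of a true QTN when it lies within 1 kb of it
on the same chromosome; every call farther than 1 kb from all true QTN is
a false positive.  The Type-1 error pools false calls across replicates:
false calls / (zero-effect SNPs x replicates), in percent.  The call
tables may come from this pipeline or, in the same schema, from external
methods, so published comparators can be scored without re-implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import LOD_SCALE
from .io import QTNCall

__all__ = [
    "EvaluationSummary",
    "empirical_power",
    "false_positive_rate",
    "effect_mse",
    "paired_t_test",
    "roc_points",
    "model_fit_criteria",
    "match_calls",
]

Truth = Sequence[tuple[str, int]]  # (chromosome, position_bp) per true QTN


@dataclass
class EvaluationSummary:
    power_per_qtn: np.ndarray
    fpr_percent: float
    mse_per_qtn: np.ndarray
    n_replicates: int
    method_label: str = "ISIS EM-BLASSO"
    failures: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.power_per_qtn = np.asarray(self.power_per_qtn, dtype=float)
        self.mse_per_qtn = np.asarray(self.mse_per_qtn, dtype=float)
        if np.any((self.power_per_qtn < 0) | (self.power_per_qtn > 1)):
            raise ValueError("power must lie in [0, 1]")
        if self.fpr_percent < 0:
            raise ValueError("false positive rate must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qtn": np.arange(1, self.power_per_qtn.size + 1),
                "power": self.power_per_qtn,
                "mse": self.mse_per_qtn,
            }
        )


def _is_match(call: QTNCall, truth: Truth, window_bp: int) -> int | None:
    """Index of the true QTN this call detects, or None."""
    for t, (chrom, pos) in enumerate(truth):
        if str(call.chromosome) == str(chrom) and abs(int(call.position_bp) - int(pos)) <= window_bp:
            return t
    return None


def match_calls(
    calls: Sequence[QTNCall], truth: Truth, window_bp: int = 1000
) -> tuple[dict[int, QTNCall], list[QTNCall]]:
    """Split one replicate's calls into {true QTN index -> best call} and
    false positives.  Multiple calls inside one truth window count as a
    single detection (the highest-LOD call) and zero false positives."""
    detected: dict[int, QTNCall] = {}
    false_calls: list[QTNCall] = []
    for c in calls:
        t = _is_match(c, truth, window_bp)
        if t is None:
            false_calls.append(c)
        elif t not in detected or c.lod > detected[t].lod:
            detected[t] = c
    return detected, false_calls


def empirical_power(
    calls_per_replicate: Sequence[Sequence[QTNCall]],
    truth: Truth,
    window_bp: int = 1000,
) -> np.ndarray:
    """Per-QTN fraction of replicates with >= 1 call within the window."""
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    hits = np.zeros(len(truth))
    for calls in calls_per_replicate:
        detected, _ = match_calls(calls, truth, window_bp)
        for t in detected:
            hits[t] += 1
    return hits / max(len(calls_per_replicate), 1)


def false_positive_rate(
    calls_per_replicate: Sequence[Sequence[QTNCall]],
    truth: Truth,
    p: int,
    window_bp: int = 1000,
) -> float:
    """Pooled false calls over (zero-effect SNPs x replicates), in percent."""
    n_rep = len(calls_per_replicate)
    if n_rep == 0:
        return 0.0
    n_false = sum(
        len(match_calls(calls, truth, window_bp)[1]) for calls in calls_per_replicate
    )
    n_zero = p - len(truth)
    return 100.0 * n_false / (n_zero * n_rep)


def effect_mse(
    estimates_per_replicate: Sequence[float | None], true_effect: float
) -> float:
    """Mean squared error over replicates in which the QTN was detected.

    Undetected replicates (None) are excluded; with zero detections the
    MSE is undefined and reported as NaN.
    """
    est = np.array([e for e in estimates_per_replicate if e is not None], dtype=float)
    if est.size == 0:
        return float("nan")
    return float(np.mean((est - true_effect) ** 2))


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical paired t test on per-QTN metric vectors (two-sided).

    Identical vectors give (0, 1); a nonzero mean difference with zero
    variance leaves t undefined (NaN, with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        warnings.warn("zero variance of nonzero differences; t undefined", RuntimeWarning)
        return float("nan"), float("nan")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def lod_threshold_for_p(p_level: float) -> float:
    """LOD cut-off equivalent to a chi-square(1) tail probability."""
    return float(stats.chi2.isf(p_level, df=1) / LOD_SCALE)


def roc_points(
    per_replicate_stats: Sequence[Sequence[QTNCall]],
    truth: Truth,
    p: int,
    thresholds: np.ndarray | None = None,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Power/Type-1-error sweep over significance levels.

    ``per_replicate_stats`` holds per-SNP LOD statistics (calls emitted at
    LOD threshold 0).  Each significance level in the grid (default 67
    log-spaced values in [1e-8, 1e-2]) maps to a LOD threshold via the
    chi-square(1) relation; calls are re-thresholded and power and pooled
    FPR recomputed.  Power is non-decreasing as the level loosens.
    """
    if thresholds is None:
        thresholds = np.geomspace(1e-8, 1e-2, 67)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty significance grid")
    rows = []
    for level in thresholds:
        lod_thr = lod_threshold_for_p(level)
        thresholded = [
            [c for c in calls if c.lod >= lod_thr] for calls in per_replicate_stats
        ]
        power = empirical_power(thresholded, truth, window_bp)
        fpr = false_positive_rate(thresholded, truth, p, window_bp)
        row = {
            "p_level": level,
            "lod_threshold": lod_thr,
            "fpr_percent": fpr,
            "power_mean": float(power.mean()),
        }
        row.update({f"power_qtn{t + 1}": pw for t, pw in enumerate(power)})
        rows.append(row)
    return pd.DataFrame(rows)


def model_fit_criteria(
    y: np.ndarray, X_selected: np.ndarray | None
) -> tuple[float, float]:
    """AIC/BIC of the OLS fit of y on intercept + detected SNP columns.

    AIC = n log(RSS/n) + 2k, BIC = n log(RSS/n) + k log(n), k = columns + 1
    (Gaussian profile form, constants dropped).  Collinear columns are
    pruned with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X_selected is None or np.size(X_selected) == 0:
        X = np.ones((n, 1))
    else:
        X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
        if X_selected.shape[0] != n:
            raise ValueError("row count of X_selected must match y")
        X = np.column_stack([np.ones(n), X_selected])
        if X.shape[1] > n:
            raise ValueError("more columns than observations")
        # prune collinear columns (keep the earliest independent ones)
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        if not keep.all():
            warnings.warn(
                f"pruned {int((~keep).sum())} collinear column(s)", RuntimeWarning
            )
            X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    k = X.shape[1]
    aic = n * np.log(rss / n) + 2 * k
    bic = n * np.log(rss / n) + k * np.log(n)
    return float(aic), float(bic)
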