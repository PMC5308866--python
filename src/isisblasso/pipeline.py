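"""End-to-end orchestration of the two-stage algorithm.

Flow: correct the phenotype for fixed effects -> iterative correlation
screening with SCAD selection (two rounds) -> EM-Bayesian-LASSO estimation
of the screened set against the ORIGINAL phenotype with the overall mean
and structure covariates as fixed effects -> LOD-based significance calls.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .association import call_qtns
from .em_blasso import EMBlassoFit, fit_em_blasso
from .evaluation import (
    EvaluationSummary,
    effect_mse,
    empirical_power,
    false_positive_rate,
    match_calls,
)
from .io import GenotypeData, PhenotypeVector, QTNCall, StructureMatrix
from .screening import ScreeningResult, correct_fixed_effects, iterative_screen
from .simulator import (
    SimulationConfig,
    resolve_qtn_indices,
    simulate_genotypes,
    simulate_phenotypes,
    total_phenotypic_variance,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_isis_em_blasso", "run_simulation_study"]


@dataclass
class PipelineConfig:
    """All tunables of the two-stage algorithm, serializable to YAML."""

    alpha_screen: float = 0.01
    isis_rounds: int = 2
    scad_gamma: float = 3.7
    scad_criterion: str = "bic"
    scad_n_lambdas: int = 100
    em_tol: float = 1e-6
    em_max_iter: int = 500
    em_prior: str = "inv_chi2"
    em_prior_params: tuple[float, float] = (0.0, 0.0)
    lod_threshold: float = 3.0
    lod_evaluation: str = "estimates"  # or "refit": profile OLS likelihoods
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_screen < 1:
            raise ValueError("alpha_screen must be in (0, 1)")
        if self.scad_gamma <= 2:
            raise ValueError("scad_gamma must exceed 2")
        if self.isis_rounds < 1:
            raise ValueError("need at least one screening round")
        if self.lod_threshold < 0:
            raise ValueError("lod_threshold must be non-negative")
        self.em_prior_params = tuple(self.em_prior_params)  # YAML loads lists

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(str(sorted(asdict(self).items())).encode()).hexdigest()[:12]


def _with_intercept(n: int, Q: StructureMatrix | None) -> np.ndarray:
    if Q is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), Q.columns])


def run_isis_em_blasso(
    geno: GenotypeData,
    pheno: PhenotypeVector,
    Q: StructureMatrix | None = None,
    config: PipelineConfig | None = None,
    lod_statistics: bool = False,
) -> tuple[list[QTNCall], EMBlassoFit, ScreeningResult]:
    """Run the full two-stage algorithm on one dataset.

    Returns (calls at the configured LOD threshold, EM fit, screening
    result).  With ``lod_statistics`` the call list instead carries every
    surviving SNP with its LOD score (threshold 0), for ROC sweeps.
    Deterministic for fixed inputs and config.
    """
    config = config or PipelineConfig()
    if len(pheno) != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    X = _with_intercept(geno.n_individuals, Q)

    y_c = correct_fixed_effects(pheno, StructureMatrix(X))
    screening = iterative_screen(
        geno,
        y_c,
        alpha=config.alpha_screen,
        n_rounds=config.isis_rounds,
        scad_gamma=config.scad_gamma,
        scad_criterion=config.scad_criterion,
        n_lambdas=config.scad_n_lambdas,
    )
    support = screening.union
    if support.size == 0:
        logger.warning("screening selected no SNPs; reporting zero QTN")
        fit = fit_em_blasso(
            X, np.empty((geno.n_individuals, 0)), pheno.values,
            tol=config.em_tol, max_iter=config.em_max_iter, prior=config.em_prior,
            prior_params=tuple(config.em_prior_params),
        )
        fit.snp_indices = support
        return [], fit, screening

    fit = fit_em_blasso(
        X,
        geno.matrix[:, support],
        pheno.values,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        prior=config.em_prior,
        prior_params=tuple(config.em_prior_params),
    )
    fit.snp_indices = support
    threshold = 0.0 if lod_statistics else config.lod_threshold
    calls = call_qtns(
        fit, geno, pheno.values, X,
        lod_threshold=threshold, evaluation=config.lod_evaluation,
    )
    logger.info(
        "stages: |K1|=%d tau1=%d tau2=%d support=%d calls=%d (seed=%s cfg=%s)",
        screening.K1.size, screening.tau1, screening.tau2,
        fit.support.size, len(calls), config.seed, config.config_hash,
    )
    return calls, fit, screening


def run_simulation_study(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
    keep_stats: bool = False,
) -> tuple[EvaluationSummary, dict]:
    """Simulate replicates, run the pipeline on each, aggregate metrics.

    Returns (summary, details); details holds per-replicate call lists,
    truth, per-QTN effect estimates and (with ``keep_stats``) the per-SNP
    LOD statistics needed for ROC sweeps.  A failing replicate is recorded
    in ``summary.failures`` and excluded from the aggregates.
    """
    pipe_config = pipe_config or PipelineConfig()
    # genotype stream deliberately disjoint from the replicate sub-seeds
    geno_seed = sim_config.seed + sim_config.n_replicates + 1
    qtn_idx = resolve_qtn_indices(sim_config)
    force_maf = np.unique(
        np.concatenate([qtn_idx, [i for pair, _ in sim_config.epistasis for i in pair]])
    ).astype(int) if sim_config.epistasis else qtn_idx
    geno = simulate_genotypes(
        sim_config.n, sim_config.p, sim_config.maf, geno_seed, qtn_indices=force_maf
    )
    if sim_config.polygenic_var > 0:
        V = total_phenotypic_variance(
            sim_config.qtn_h2, sim_config.residual_var, sim_config.polygenic_var,
            tuple(v for _, v in sim_config.epistasis),
        )
        logger.info("polygenic heritability h2_poly = %.3f", sim_config.polygenic_var / V)
    replicates = simulate_phenotypes(geno, sim_config)
    truth = [
        (str(c), int(p))
        for c, p in zip(replicates[0].true_chromosomes, replicates[0].true_positions)
    ]
    true_effects = [replicates[0].true_effects[int(i)] for i in qtn_idx]

    calls_per_rep: list[list[QTNCall]] = []
    stats_per_rep: list[list[QTNCall]] = []
    estimates: list[list[float | None]] = [[] for _ in truth]
    failures: list[int] = []
    for r, rep in enumerate(replicates):
        try:
            calls, _, _ = run_isis_em_blasso(
                geno,
                PhenotypeVector(rep.phenotypes),
                config=pipe_config,
                lod_statistics=keep_stats,
            )
        except Exception:
            logger.exception("replicate %d failed", r)
            failures.append(r)
            continue
        if keep_stats:
            stats_per_rep.append(calls)
            calls = [c for c in calls if c.lod >= pipe_config.lod_threshold]
        calls_per_rep.append(calls)
        detected, _ = match_calls(calls, truth)
        for t in range(len(truth)):
            estimates[t].append(detected[t].effect if t in detected else None)

    power = empirical_power(calls_per_rep, truth)
    fpr = false_positive_rate(calls_per_rep, truth, sim_config.p)
    mse = np.array(
        [effect_mse(est, eff) for est, eff in zip(estimates, true_effects)]
    )
    summary = EvaluationSummary(
        power_per_qtn=power,
        fpr_percent=fpr,
        mse_per_qtn=mse,
        n_replicates=len(calls_per_rep),
        failures=failures,
    )
    details = {
        "genotypes": geno,
        "truth": truth,
        "true_effects": true_effects,
        "calls_per_replicate": calls_per_rep,
        "estimates_per_qtn": estimates,
        "lod_stats_per_replicate": stats_per_rep if keep_stats else None,
    }
    return summary, details
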