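"""Model/Results front-end for the two-stage multi-locus GWAS.

`IsisEmBlasso` is constructed from data (or files) and `fit()` returns an
`IsisEmBlassoResults` carrying the significant calls, shrunken effect
estimates with their posterior standard errors, the screening diagnostics
and a text `summary()` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import io
from .em_blasso import EMBlassoFit
from .evaluation import model_fit_criteria
from .io import GenotypeData, PhenotypeVector, QTNCall, StructureMatrix
from .pipeline import PipelineConfig, run_isis_em_blasso
from .screening import ScreeningResult

__all__ = ["IsisEmBlasso", "IsisEmBlassoResults"]


class IsisEmBlasso:
    """Multi-locus GWAS model: iterative correlation screening + SCAD
    selection, then EM-Bayesian-LASSO estimation and LOD testing.

    Parameters
    ----------
    genotypes : GenotypeData
        n x p coded SNP matrix with its map.
    phenotype : PhenotypeVector or array-like
        Trait values, one per line, genotype row order.
    structure : StructureMatrix, optional
        Population-structure (or other fixed-effect) covariates; an
        intercept is always included automatically.
    config : PipelineConfig, optional
        Algorithm tunables (screen level 0.01, SCAD gamma 3.7, LOD
        threshold 3 by default).
    """

    def __init__(
        self,
        genotypes: GenotypeData,
        phenotype: PhenotypeVector | np.ndarray,
        structure: StructureMatrix | None = None,
        config: PipelineConfig | None = None,
    ):
        self.genotypes = genotypes
        self.phenotype = (
            phenotype
            if isinstance(phenotype, PhenotypeVector)
            else PhenotypeVector(np.asarray(phenotype, dtype=float))
        )
        self.structure = structure
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(
        cls,
        genotype_path,
        map_path,
        phenotype_path,
        structure_path=None,
        coding: str = "zero_one",
        impute: bool = False,
        config: PipelineConfig | None = None,
    ) -> "IsisEmBlasso":
        geno = io.read_genotype_matrix(genotype_path, map_path, coding=coding, impute=impute)
        pheno = io.read_phenotype(phenotype_path)
        Q = io.read_structure(structure_path) if structure_path else None
        return cls(geno, pheno, structure=Q, config=config)

    def fit(self, **overrides) -> "IsisEmBlassoResults":
        """Run both stages; keyword overrides patch the config for this fit."""
        config = replace(self.config, **overrides) if overrides else self.config
        calls, em_fit, screening = run_isis_em_blasso(
            self.genotypes, self.phenotype, Q=self.structure, config=config
        )
        return IsisEmBlassoResults(self, calls, em_fit, screening, config)


class IsisEmBlassoResults:
    """Fitted state: significant calls, effect posteriors, diagnostics."""

    def __init__(
        self,
        model: IsisEmBlasso,
        calls: list[QTNCall],
        em_fit: EMBlassoFit,
        screening: ScreeningResult,
        config: PipelineConfig,
    ):
        self.model = model
        self.calls = calls
        self.em_fit = em_fit
        self.screening = screening
        self.config = config

    @property
    def effects(self) -> pd.Series:
        """Shrunken effect estimates of all surviving (nonzero) SNPs."""
        idx = np.asarray(self.em_fit.snp_indices)[self.em_fit.support]
        return pd.Series(
            self.em_fit.gamma_hat[self.em_fit.support],
            index=[str(s) for s in self.model.genotypes.snp_ids[idx]],
            name="effect",
        )

    @property
    def effect_se(self) -> pd.Series:
        """Posterior standard errors (sqrt prediction error) of the survivors."""
        idx = np.asarray(self.em_fit.snp_indices)[self.em_fit.support]
        return pd.Series(
            np.sqrt(self.em_fit.var_gamma[self.em_fit.support]),
            index=[str(s) for s in self.model.genotypes.snp_ids[idx]],
            name="se",
        )

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": c.snp_id,
                    "chromosome": c.chromosome,
                    "position_bp": c.position_bp,
                    "effect": c.effect,
                    "lod": c.lod,
                    "r2_percent": c.r2_percent,
                }
                for c in self.calls
            ]
        )

    def information_criteria(self) -> tuple[float, float]:
        """(AIC, BIC) of the OLS fit of the trait on the called SNPs."""
        geno = self.model.genotypes
        cols = [
            int(np.where(geno.snp_ids == c.snp_id)[0][0]) for c in self.calls
        ]
        X = geno.matrix[:, cols] if cols else None
        return model_fit_criteria(self.model.phenotype.values, X)

    def annotate(self, genes: io.GeneTable, window_bp: int = 30_000) -> "IsisEmBlassoResults":
        """Return results with candidate genes attached to each call."""
        annotated = io.annotate_candidate_genes(self.calls, genes, window_bp)
        return IsisEmBlassoResults(
            self.model, annotated, self.em_fit, self.screening, self.config
        )

    def to_report(self, path) -> None:
        io.write_qtn_report(self.calls, path)

    def summary(self) -> str:
        geno = self.model.genotypes
        s = self.screening
        lines = [
            "ISIS EM-BLASSO multi-locus GWAS results",
            "=" * 72,
            f"individuals: {geno.n_individuals}    SNPs: {geno.n_snps}"
            f"    monomorphic: {int(geno.monomorphic.sum())}",
            f"screen level: {self.config.alpha_screen}    SCAD gamma: "
            f"{self.config.scad_gamma}    LOD threshold: {self.config.lod_threshold}",
            f"screened |K1|={s.K1.size}  tau1={s.tau1}  tau2={s.tau2}"
            f"  EM survivors={self.em_fit.support.size}  calls={len(self.calls)}",
            f"residual variance: {self.em_fit.sigma2:.4g}"
            f"    EM iterations: {self.em_fit.n_iter}"
            f" ({'converged' if self.em_fit.converged else 'NOT converged'})",
            "-" * 72,
        ]
        if self.calls:
            lines.append(
                f"{'snp_id':<14}{'chr':<5}{'position':>12}{'effect':>10}"
                f"{'LOD':>8}{'r2(%)':>8}"
            )
            for c in self.calls:
                lines.append(
                    f"{c.snp_id:<14}{c.chromosome:<5}{c.position_bp:>12}"
                    f"{c.effect:>10.4f}{c.lod:>8.2f}{c.r2_percent:>8.2f}"
                )
        else:
            lines.append("no SNP reached the LOD threshold")
        return "\n".join(lines)
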