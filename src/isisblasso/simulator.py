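"""Monte-Carlo simulation of the three benchmark experiments.

The generator emulates a diversity panel of 199 fully homozygous inbred
lines genotyped at 10000 biallelic SNPs (2000 per chromosome on five
chromosomes).  Six QTN are placed on SNPs with allele frequency 0.30 and
assigned heritabilities (0.10, 0.05, 0.05, 0.15, 0.05, 0.05); phenotypes
have overall mean 10 and residual variance 10.  Experiment 2 adds an
additive polygenic background MVN(0, K s2_poly) with s2_poly = 2 (so the
polygenic heritability is 2 / (12/0.55) = 0.092); experiment 3 instead
adds three epistatic pairs each contributing variance 1.25 (heritability
1.25 / 25 = 0.05 apiece).

Synthetic genotypes are drawn in linkage equilibrium; to reproduce a real
panel's LD structure, pass a genotype file through the pipeline instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenotypeData

__all__ = [
    "SimulationConfig",
    "KinshipMatrix",
    "SimulatedReplicate",
    "simulate_genotypes",
    "compute_kinship",
    "total_phenotypic_variance",
    "qtn_effect_from_h2",
    "simulate_phenotypes",
    "write_simulated_dataset",
    "read_simulated_phenotypes",
]

DEFAULT_QTN_H2 = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
DEFAULT_EPISTASIS_VAR = 1.25
N_CHROMOSOMES = 5
SNP_SPACING_BP = 10_000


@dataclass
class SimulationConfig:
    """Parameters of one simulation experiment."""

    n: int = 199
    p: int = 10_000
    maf: float = 0.30
    qtn_snps: tuple[int, ...] | None = None  # auto-placed when None
    qtn_h2: tuple[float, ...] = DEFAULT_QTN_H2
    qtn_effect_signs: tuple[int, ...] | None = None  # all +1 when None
    mean: float = 10.0
    residual_var: float = 10.0
    polygenic_var: float = 0.0
    epistasis: tuple[tuple[tuple[int, int], float], ...] = ()
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.residual_var <= 0:
            raise ValueError("residual variance must be positive")
        if self.polygenic_var < 0:
            raise ValueError("polygenic variance must be non-negative")
        h2 = np.asarray(self.qtn_h2, dtype=float)
        if np.any(h2 <= 0) or np.any(h2 >= 1) or h2.sum() >= 1:
            raise ValueError("per-QTN heritabilities must be in (0,1) with sum < 1")
        for (i, j), v in self.epistasis:
            if v <= 0:
                raise ValueError(f"epistatic variance for pair ({i},{j}) must be > 0")
        if self.qtn_snps is not None and len(self.qtn_snps) != len(self.qtn_h2):
            raise ValueError("qtn_snps and qtn_h2 lengths differ")

    @classmethod
    def experiment(cls, number: int, **overrides) -> "SimulationConfig":
        """The three benchmark setups: 1 = QTN only, 2 = + polygenic
        background (variance 2), 3 = + three epistatic pairs (1.25 each)."""
        if number == 1:
            extra = {}
        elif number == 2:
            extra = {"polygenic_var": 2.0}
        elif number == 3:
            extra = {"epistasis": None}  # placed after QTN positions are known
        else:
            raise ValueError("experiment number must be 1, 2 or 3")
        cfg = cls(**{**extra, **overrides}) if number != 3 else None
        if number == 3:
            ov = dict(overrides)
            epi = ov.pop("epistasis", None)
            cfg = cls(**ov)
            if epi is None:
                # three pairs of interacting loci, distinct from the six
                # additive QTN, spread deterministically over the genome
                taken = set(resolve_qtn_indices(cfg).tolist())
                loci: list[int] = []
                for f in np.linspace(0.15, 0.85, 6):
                    j = int(f * (cfg.p - 1))
                    while j in taken:
                        j += 1
                    taken.add(j)
                    loci.append(j)
                epi = tuple(
                    ((loci[2 * i], loci[2 * i + 1]), DEFAULT_EPISTASIS_VAR)
                    for i in range(3)
                )
            cfg.epistasis = epi
        return cfg


def resolve_qtn_indices(config: SimulationConfig) -> np.ndarray:
    """QTN column indices: the configured ones, or deterministic placement
    spread over the genome (fractions of p on alternating chromosomes)."""
    if config.qtn_snps is not None:
        idx = np.asarray(config.qtn_snps, dtype=int)
        if np.any(idx < 0) or np.any(idx >= config.p):
            raise ValueError("QTN index out of range")
        return idx
    fracs = np.linspace(0.08, 0.92, len(config.qtn_h2))
    return np.unique((fracs * (config.p - 1)).astype(int))


@dataclass
class KinshipMatrix:
    """Marker-based relatedness, K = W W'/p with W column-standardized."""

    values: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = K


@dataclass
class SimulatedReplicate:
    """One simulated phenotype draw with its generating truth."""

    phenotypes: np.ndarray
    true_effects: dict[int, float]
    true_positions: np.ndarray
    true_chromosomes: np.ndarray
    components: dict[str, float] = field(default_factory=dict)


def simulate_genotypes(
    n: int,
    p: int,
    maf: float,
    seed: int,
    qtn_indices: np.ndarray | None = None,
) -> GenotypeData:
    """Draw an inbred-line genotype panel in linkage equilibrium.

    QTN columns get allele frequency exactly ``maf``; background columns
    draw frequencies uniformly from [0.05, 0.5].  SNPs sit on five
    synthetic chromosomes, p/5 each, uniformly spaced 10 kb apart.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n < 2 or p < N_CHROMOSOMES:
        raise ValueError("need n >= 2 individuals and p >= 5 SNPs")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.5, size=p)
    if qtn_indices is not None:
        freqs[np.asarray(qtn_indices, int)] = maf
    mat = (rng.random((n, p)) < freqs).astype(float)

    per_chrom = int(np.ceil(p / N_CHROMOSOMES))
    chrom = np.array([str(1 + j // per_chrom) for j in range(p)], dtype=object)
    pos = np.array(
        [SNP_SPACING_BP * (1 + j % per_chrom) for j in range(p)], dtype=np.int64
    )
    ids = np.array([f"snp{j + 1:05d}" for j in range(p)], dtype=object)
    return GenotypeData(
        matrix=mat, snp_ids=ids, chromosome=chrom, position_bp=pos, coding="zero_one"
    )


def compute_kinship(geno: GenotypeData) -> KinshipMatrix:
    """VanRaden-style relatedness from column-standardized markers."""
    poly = ~geno.monomorphic
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs for kinship")
    W = geno.matrix[:, poly]
    W = (W - W.mean(axis=0)) / W.std(axis=0, ddof=1)
    K = W @ W.T / W.shape[1]
    return KinshipMatrix(K)


def total_phenotypic_variance(
    qtn_h2: tuple[float, ...],
    residual_var: float,
    polygenic_var: float = 0.0,
    epi_vars: tuple[float, ...] = (),
) -> float:
    """Total variance V implied by the configured components.

    Solves sum(h2) V + s2_poly + sum(s2_epi) + s2 = V, i.e.
    V = (s2 + s2_poly + sum s2_epi) / (1 - sum h2).
    """
    h2_sum = float(np.sum(qtn_h2))
    if h2_sum >= 1:
        raise ValueError("QTN heritabilities sum to >= 1; infeasible")
    return (residual_var + polygenic_var + float(np.sum(epi_vars))) / (1 - h2_sum)


def qtn_effect_from_h2(h2: float, geno_var: float, total_var: float) -> float:
    """Additive effect magnitude a with a^2 var(x) = h2 V."""
    if h2 <= 0 or h2 >= 1 or geno_var <= 0 or total_var <= 0:
        raise ValueError("h2 in (0,1) and positive variances required")
    return float(np.sqrt(h2 * total_var / geno_var))


def simulate_phenotypes(
    geno: GenotypeData, config: SimulationConfig
) -> list[SimulatedReplicate]:
    """Draw ``config.n_replicates`` phenotype vectors on a fixed panel.

    y = mean + sum_q a_q x_q + polygenic + epistatic + e, with effects
    calibrated against the empirical column variances so realized
    heritabilities match the configured ones on average.  Replicate r uses
    the sub-seed config.seed + r; within a replicate the residual noise is
    drawn before the polygenic deviation, so the noise stream does not
    depend on the marker panel.
    """
    qtn = resolve_qtn_indices(config)
    h2 = np.asarray(config.qtn_h2, dtype=float)
    epi_vars = tuple(v for _, v in config.epistasis)
    V = total_phenotypic_variance(
        tuple(h2), config.residual_var, config.polygenic_var, epi_vars
    )

    Xq = geno.matrix[:, qtn]
    geno_var = Xq.var(axis=0, ddof=1)
    if np.any(geno_var == 0):
        raise ValueError("a QTN column is monomorphic in this panel")
    signs = (
        np.asarray(config.qtn_effect_signs, dtype=float)
        if config.qtn_effect_signs is not None
        else np.ones(h2.size)
    )
    effects = signs * np.array(
        [qtn_effect_from_h2(h, g, V) for h, g in zip(h2, geno_var)]
    )
    additive = Xq @ effects

    epi_term = np.zeros(geno.n_individuals)
    for (i, j), s2e in config.epistasis:
        xi = geno.matrix[:, i] - geno.matrix[:, i].mean()
        xj = geno.matrix[:, j] - geno.matrix[:, j].mean()
        w = xi * xj
        vw = w.var(ddof=1)
        if vw == 0:
            raise ValueError(f"epistatic pair ({i},{j}) has zero interaction variance")
        epi_term = epi_term + np.sqrt(s2e / vw) * w

    L = None
    if config.polygenic_var > 0:
        K = compute_kinship(geno).values
        L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))

    true_effects = {int(c): float(e) for c, e in zip(qtn, effects)}
    replicates = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + r)
        eps = rng.normal(0.0, np.sqrt(config.residual_var), size=geno.n_individuals)
        poly = (
            np.sqrt(config.polygenic_var)
            * (L @ rng.normal(size=geno.n_individuals))
            if L is not None
            else np.zeros(geno.n_individuals)
        )
        y = config.mean + additive + poly + epi_term + eps
        replicates.append(
            SimulatedReplicate(
                phenotypes=y,
                true_effects=true_effects,
                true_positions=geno.position_bp[qtn].copy(),
                true_chromosomes=geno.chromosome[qtn].copy(),
                components={
                    "additive": float(additive.var(ddof=1)),
                    "polygenic": float(poly.var(ddof=1)),
                    "epistatic": float(epi_term.var(ddof=1)),
                    "residual": float(eps.var(ddof=1)),
                    "total_theoretical": V,
                },
            )
        )
    return replicates


def write_simulated_dataset(
    geno: GenotypeData, replicates: list[SimulatedReplicate], out_dir
) -> None:
    """Persist a simulated study as delimited text.

    Writes ``genotypes.tsv`` + ``snp_map.tsv`` (the panel) and
    ``phenotypes.tsv``, a long-format table with one row per (replicate,
    individual) so the stacked-replicate sheets can be rebuilt exactly.
    """
    import pandas as pd

    from .io import write_genotype_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(geno, out / "genotypes.tsv", out / "snp_map.tsv")
    rows = []
    for r, rep in enumerate(replicates):
        for i, v in enumerate(rep.phenotypes):
            rows.append((r, i, v))
    pd.DataFrame(rows, columns=["replicate", "individual", "phenotype"]).to_csv(
        out / "phenotypes.tsv", sep="\t", index=False
    )


def read_simulated_phenotypes(path) -> list[np.ndarray]:
    """Rebuild per-replicate phenotype vectors from the long-format table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        sub.sort_values("individual")["phenotype"].to_numpy()
        for _, sub in df.groupby("replicate")
    ]
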