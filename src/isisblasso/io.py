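"""Reading, validation and reporting of genotype/phenotype/annotation data.

Genotype matrices are delimited text (comma or tab), one row per inbred
line, one column per SNP, with a header row of SNP identifiers.  A separate
map file carries (snp_id, chromosome, position_bp).  Inbred lines are fully
homozygous, so each SNP is coded with two values: ``{0, 1}`` by default or
``{-1, +1}``.  Downstream methods standardize columns, so the two codings
are statistically equivalent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "PhenotypeVector",
    "StructureMatrix",
    "GeneRecord",
    "GeneTable",
    "QTNCall",
    "read_genotype_matrix",
    "read_phenotype",
    "read_structure",
    "read_gene_table",
    "write_qtn_report",
    "read_qtn_report",
    "annotate_candidate_genes",
]

CODING_SETS = {
    "zero_one": (0.0, 1.0),
    "minus_plus_one": (-1.0, 1.0),
}


@dataclass
class GenotypeData:
    """An n x p matrix of SNP codes with its marker map.

    ``monomorphic`` flags zero-sample-variance columns; they are kept in the
    matrix (so column indices match the map) but excluded from screening.
    """

    matrix: np.ndarray
    snp_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    coding: str = "zero_one"
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if self.coding not in CODING_SETS:
            raise ValueError(f"unknown coding {self.coding!r}")
        n, p = self.matrix.shape
        for name, arr in (
            ("snp_ids", self.snp_ids),
            ("chromosome", self.chromosome),
            ("position_bp", self.position_bp),
        ):
            if len(arr) != p:
                raise ValueError(f"{name} has length {len(arr)}, expected {p} SNPs")
        if np.any(self.position_bp <= 0):
            raise ValueError("position_bp must be positive")
        if np.isnan(self.matrix).any():
            raise ValueError("genotype matrix contains missing values")
        legal = CODING_SETS[self.coding]
        bad = ~np.isin(self.matrix, legal)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.matrix[i, j]!r} at row {i + 1}, column "
                f"{self.snp_ids[j]!r} is not in the {self.coding} coding set"
            )
        if self.monomorphic is None:
            self.monomorphic = self.matrix.var(axis=0) == 0.0
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PhenotypeVector:
    """A finite trait vector, one value per individual (genotype row order)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("phenotype vector is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StructureMatrix:
    """Fixed-effect covariates (e.g. population-structure components)."""

    columns: np.ndarray
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.ndim != 2:
            raise ValueError("structure matrix must be 2-D")
        n, q = self.columns.shape
        if np.linalg.matrix_rank(self.columns) < q:
            raise ValueError("structure matrix is rank deficient")
        if self.names is None:
            self.names = [f"Q{j + 1}" for j in range(q)]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start_bp > end_bp")


@dataclass
class GeneTable:
    """1-based inclusive gene intervals (GFF3 convention)."""

    records: list[GeneRecord]


@dataclass
class QTNCall:
    """A significant SNP: its effect, LOD score and variance contribution."""

    snp_id: str
    chromosome: str
    position_bp: int
    effect: float
    lod: float
    r2_percent: float
    genes: list[tuple[GeneRecord, int]] = field(default_factory=list)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        sample = fh.readline()
    return "," if sample.count(",") >= sample.count("\t") else "\t"


def read_genotype_matrix(
    path: str | Path,
    map_path: str | Path,
    coding: str = "zero_one",
    impute: bool = False,
) -> GenotypeData:
    """Load a genotype matrix and its SNP map.

    Missing cells (empty or NA) are replaced, when ``impute`` is on, by the
    column mean rounded to the nearest legal code, ties going to the larger
    code.  Monomorphic columns are flagged, never dropped.
    """
    path, map_path = Path(path), Path(map_path)
    if coding not in CODING_SETS:
        raise ValueError(f"unknown coding {coding!r}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), na_values=["NA", "na", ""])
    snp_ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)

    mp = pd.read_csv(map_path, sep=_sniff_delimiter(map_path))
    required = {"snp_id", "chromosome", "position_bp"}
    if not required.issubset(mp.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    mp = mp.set_index(mp["snp_id"].astype(str))
    missing_ids = [s for s in snp_ids if s not in mp.index]
    if missing_ids or len(mp) != len(snp_ids):
        raise ValueError(
            f"genotype/map mismatch: {len(snp_ids)} SNPs in matrix, "
            f"{len(mp)} in map, {len(missing_ids)} matrix SNPs absent from map"
        )
    mp = mp.loc[snp_ids]

    nan_mask = np.isnan(mat)
    if nan_mask.any():
        if not impute:
            i, j = np.argwhere(nan_mask)[0]
            raise ValueError(
                f"missing genotype at row {i + 1}, SNP {snp_ids[j]!r} "
                "(enable imputation or clean the input)"
            )
        codes = np.array(CODING_SETS[coding])
        for j in np.where(nan_mask.any(axis=0))[0]:
            col = mat[:, j]
            m = col[~nan_mask[:, j]]
            if m.size == 0:
                raise ValueError(f"SNP {snp_ids[j]!r} is entirely missing")
            # nearest legal code; ties broken toward the larger code
            d = np.abs(codes - m.mean())
            fill = codes[np.where(d == d.min())[0].max()]
            col[nan_mask[:, j]] = fill

    return GenotypeData(
        matrix=mat,
        snp_ids=np.array(snp_ids, dtype=object),
        chromosome=mp["chromosome"].astype(str).to_numpy(dtype=object),
        position_bp=mp["position_bp"].to_numpy(dtype=np.int64),
        coding=coding,
    )


def write_genotype_matrix(geno: GenotypeData, path: str | Path, map_path: str | Path) -> None:
    """Inverse of :func:`read_genotype_matrix` (tab-delimited)."""
    ids = [str(s) for s in geno.snp_ids]
    pd.DataFrame(geno.matrix, columns=ids).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"snp_id": ids, "chromosome": geno.chromosome, "position_bp": geno.position_bp}
    ).to_csv(map_path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read one trait value per line, genotype row order."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric phenotype {line!r} on line {lineno}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite phenotype on line {lineno}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: empty phenotype file")
    return PhenotypeVector(np.array(values))


def read_structure(path: str | Path) -> StructureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    return StructureMatrix(df.to_numpy(dtype=float), names=[str(c) for c in df.columns])


def read_gene_table(path: str | Path) -> GeneTable:
    """Read gene features from GFF3 (only ``gene`` records are consumed)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id])[0]
        records.append(
            GeneRecord(
                gene_id=g.id,
                gene_name=name,
                chromosome=str(g.seqid),
                start_bp=int(g.start),
                end_bp=int(g.end),
            )
        )
    return GeneTable(records)


_REPORT_COLUMNS = [
    "snp_id",
    "chromosome",
    "position_bp",
    "effect",
    "lod",
    "r2_percent",
    "gene_id",
    "gene_name",
    "distance_bp",
]


def write_qtn_report(calls: Iterable[QTNCall], path: str | Path) -> None:
    """Write calls as a tab-delimited table ordered by (chromosome, position).

    A call annotated with g genes occupies g rows (one per gene); an
    unannotated call occupies one row with empty gene columns.
    """
    rows = []
    for c in sorted(calls, key=lambda c: (str(c.chromosome), int(c.position_bp))):
        base = [c.snp_id, c.chromosome, c.position_bp,
                repr(float(c.effect)), repr(float(c.lod)), repr(float(c.r2_percent))]
        if c.genes:
            for gene, dist in c.genes:
                rows.append(base + [gene.gene_id, gene.gene_name, dist])
        else:
            rows.append(base + ["", "", ""])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_REPORT_COLUMNS)
        w.writerows(rows)


def read_qtn_report(path: str | Path) -> list[QTNCall]:
    """Read a call table in the :func:`write_qtn_report` schema.

    Also accepts tables from external methods, as long as the first six
    columns follow the schema.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    calls: dict[tuple, QTNCall] = {}
    for _, r in df.iterrows():
        key = (str(r["snp_id"]), str(r["chromosome"]), int(r["position_bp"]))
        if key not in calls:
            calls[key] = QTNCall(
                snp_id=key[0],
                chromosome=key[1],
                position_bp=key[2],
                effect=float(r["effect"]),
                lod=float(r["lod"]),
                r2_percent=float(r["r2_percent"]),
            )
        if "gene_id" in df.columns and isinstance(r.get("gene_id"), str) and r["gene_id"]:
            dist = int(r["distance_bp"])
            pos = key[2]
            # reconstruct the interval end nearest the SNP; start/end beyond
            # the stored distance are unknown, record a degenerate interval
            if dist == 0:
                start = end = pos
            elif dist < 0:
                start = end = pos + dist
            else:
                start = end = pos + dist
            calls[key].genes.append(
                (GeneRecord(str(r["gene_id"]), str(r["gene_name"]), key[1], start, end), dist)
            )
    return list(calls.values())


def signed_gene_distance(position_bp: int, gene: GeneRecord) -> int:
    """Signed SNP-to-gene distance: 0 inside the gene, negative when the
    gene interval precedes the SNP along the chromosome, positive after."""
    if gene.start_bp <= position_bp <= gene.end_bp:
        return 0
    if gene.end_bp < position_bp:
        return -(position_bp - gene.end_bp)
    return gene.start_bp - position_bp


def annotate_candidate_genes(
    calls: Sequence[QTNCall], genes: GeneTable, window_bp: int = 30_000
) -> list[QTNCall]:
    """Attach genes whose interval lies within ``window_bp`` of each call.

    Returns new call objects; annotation order is (start_bp, gene_id), so
    the result does not depend on the order of the gene table.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    out = []
    for c in calls:
        hits = []
        for g in genes.records:
            if str(g.chromosome) != str(c.chromosome):
                continue
            d = signed_gene_distance(int(c.position_bp), g)
            if abs(d) <= window_bp:
                hits.append((g, d))
        hits.sort(key=lambda t: (t[0].start_bp, t[0].gene_id))
        out.append(replace(c, genes=hits))
    return out
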