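"""Gene-wise aggregation of SNP p-values and the gene-level drift threshold.

SNPs are restricted to those falling inside annotated gene intervals, each
gene is scored by the plain arithmetic mean of its SNPs' raw CMH p-values,
genes with too few SNPs (default: fewer than 20) are excluded, and a gene
counts as selected when its mean p falls strictly below an extreme lower
quantile of the same score computed on the drift comparison.

Annotation is accepted as BED (0-based half-open, converted on read) or
GFF3 gene features; internally all intervals are 1-based inclusive, and a
SNP belongs to every gene whose interval contains it (overlapping genes
each receive it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .scan import ScanResult, empirical_quantile

__all__ = [
    "GeneModel",
    "GeneScore",
    "read_bed",
    "read_gff3",
    "write_bed",
    "assign_snps_to_genes",
    "gene_mean_p",
    "gene_drift_threshold",
    "significant_genes",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; coordinates are 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    n_snps: int
    mean_p: float


def read_bed(path) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    genes = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"gene_{lineno}"
            genes.append(GeneModel(name, chrom, start0 + 1, end0))
    return genes


def write_bed(genes, path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            handle.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def read_gff3(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene features from GFF3 (already 1-based inclusive)."""
    genes = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            if fields[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or f"gene_{lineno}"
            genes.append(GeneModel(name, fields[0], int(fields[3]), int(fields[4])))
    return genes


def assign_snps_to_genes(scan_result: ScanResult, genes) -> dict:
    """Map gene_id -> DataFrame of the scan SNPs inside that gene's interval.

    Overlapping genes each receive shared SNPs; intergenic SNPs are left
    unassigned.  Annotation chromosomes absent from the scan produce a
    warning, not an error.
    """
    scan_chroms = set(pd.unique(scan_result.data["chrom"]))
    missing = {g.chromosome for g in genes} - scan_chroms
    if missing:
        warnings.warn(
            f"annotation chromosomes absent from scan: {sorted(missing)}",
            RuntimeWarning,
            stacklevel=2,
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes `end` inclusive.
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    hits: dict[str, list[int]] = {}
    chrom_arr = scan_result.data["chrom"].to_numpy()
    pos_arr = scan_result.data["pos"].to_numpy()
    for row, (chrom, pos) in enumerate(zip(chrom_arr, pos_arr)):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(int(pos)):
            hits.setdefault(iv.data, []).append(row)
    return {
        gene_id: scan_result.data.iloc[rows]
        for gene_id, rows in hits.items()
    }


def gene_mean_p(assignment: dict, min_snps: int = 20, strict: bool = False) -> list[GeneScore]:
    """Arithmetic mean of raw SNP p-values per gene.

    Genes qualify with ``n_snps >= min_snps`` by default; ``strict=True``
    switches to a strictly-greater rule (both readings of a "more than 20
    SNPs" criterion are supported).
    """
    scores = []
    for gene_id, snps in assignment.items():
        n = len(snps)
        keep = n > min_snps if strict else n >= min_snps
        if keep and n >= 1:
            scores.append(GeneScore(gene_id, n, float(snps["p"].mean())))
    return sorted(scores, key=lambda s: s.gene_id)


def gene_drift_threshold(drift_gene_scores, q: float = 1e-5) -> float:
    """Lower q-quantile of drift-comparison gene mean-p values.

    The drift scores must come from the same assignment and ``min_snps``
    rule as the scores the threshold will be applied to.
    """
    if not drift_gene_scores:
        raise ValueError("no drift gene scores")
    values = np.array([s.mean_p for s in drift_gene_scores])
    threshold, _ = empirical_quantile(values, q)
    return threshold


def significant_genes(scores, threshold: float) -> list[str]:
    """Gene ids with mean p strictly below the gene-level drift threshold."""
    return [s.gene_id for s in scores if s.mean_p < threshold]


def scores_to_frame(scores) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "n_snps": [s.n_snps for s in scores],
            "mean_p": [s.mean_p for s in scores],
        }
    )
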