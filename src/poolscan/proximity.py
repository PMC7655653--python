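"""Δdistance randomization test: are selected SNPs near expression-responsive genes?

For a set of selected SNPs and a focal gene set (e.g. genes whose protein
or transcript expression responds to the thermal regimes), the observed
statistic is the mean, over SNPs, of the base-pair distance to the nearest
focal gene (0 for a SNP inside a gene, otherwise distance to the nearer
interval edge).  The null reference repeats the measurement for many
random gene sets of the same size drawn uniformly without replacement from
the whole annotation.  Δdistance = observed mean − each random-set mean;
a 95% interval of Δ entirely below zero indicates the selected SNPs sit
closer to the focal genes than chance expects (putative physical linkage).

Random sets are drawn genome-wide by default (per-chromosome summaries
still evaluate distances chromosome by chromosome); a chromosome-stratified
draw and a midpoint-based distance are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistanceResult", "snp_to_geneset_distance", "delta_distance_test"]


@dataclass
class DistanceResult:
    """Observed vs. randomized mean SNP-to-nearest-gene distances."""

    label: str
    chromosome: str  # "genome" for the pooled result
    observed_mean: float
    randomized_means: np.ndarray  # (n_random,)
    delta: np.ndarray  # observed - randomized, (n_random,)
    median_delta: float
    ci_low: float  # central 95% interval of delta
    ci_high: float
    n_snps: int

    @property
    def excludes_zero(self) -> bool:
        return self.ci_high < 0.0 or self.ci_low > 0.0


def _edge_distance(pos: int, start: int, end: int, midpoint: bool) -> int:
    if midpoint:
        return abs(pos - (start + end) // 2)
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def snp_to_geneset_distance(snp_position: int, chromosome: str, gene_set, midpoint: bool = False):
    """Distance (bp) from one SNP to the nearest gene of a set.

    Returns ``None`` when the set has no gene on the SNP's chromosome
    (the SNP is then excluded from mean distances, with a log entry at the
    caller).
    """
    best = None
    for g in gene_set:
        if g.chromosome != chromosome:
            continue
        d = _edge_distance(snp_position, g.start, g.end, midpoint)
        if best is None or d < best:
            best = d
    return best


def _distance_matrices(snps, genes, midpoint: bool):
    """Per-chromosome (n_snps_c x n_genes_all) distance matrices.

    ``snps`` is a sequence of (chromosome, position); ``genes`` the full
    annotation.  Gene columns are indexed by position in ``genes``.
    """
    by_chrom: dict[str, dict] = {}
    for j, g in enumerate(genes):
        entry = by_chrom.setdefault(g.chromosome, {"cols": [], "start": [], "end": []})
        entry["cols"].append(j)
        entry["start"].append(g.start)
        entry["end"].append(g.end)
    mats = {}
    for chrom, entry in by_chrom.items():
        pos = np.array([p for c, p in snps if c == chrom], dtype=np.int64)
        if len(pos) == 0:
            continue
        start = np.array(entry["start"], dtype=np.int64)
        end = np.array(entry["end"], dtype=np.int64)
        if midpoint:
            mid = (start + end) // 2
            d = np.abs(pos[:, None] - mid[None, :])
        else:
            below = start[None, :] - pos[:, None]  # >0 when SNP left of gene
            above = pos[:, None] - end[None, :]  # >0 when SNP right of gene
            d = np.maximum(np.maximum(below, above), 0)
        mats[chrom] = {"D": d.astype(np.float64), "cols": np.array(entry["cols"])}
    return mats


def delta_distance_test(
    selected_snps,
    focal_genes,
    all_genes,
    n_random: int = 10_000,
    seed: int | None = None,
    *,
    per_chromosome: bool = False,
    stratified: bool = False,
    midpoint: bool = False,
    label: str = "",
):
    """Δdistance randomization test.

    Parameters
    ----------
    selected_snps : sequence of (chromosome, position) pairs (or a
        DataFrame with ``chrom``/``pos`` columns).
    focal_genes : the gene set whose proximity to the SNPs is tested.
    all_genes : annotation pool the random sets are drawn from.
    n_random : number of random gene sets, each of size ``len(focal_genes)``.
    per_chromosome : additionally return one result per chromosome
        (random sets remain genome-wide unless ``stratified``).
    stratified : draw random sets per chromosome, preserving the focal
        set's per-chromosome composition.

    Returns a :class:`DistanceResult`, or ``{chromosome: DistanceResult}``
    including the ``"genome"`` pooled entry when ``per_chromosome`` is set.
    """
    if hasattr(selected_snps, "columns"):
        selected_snps = list(zip(selected_snps["chrom"], selected_snps["pos"]))
    selected_snps = list(selected_snps)
    focal_genes = list(focal_genes)
    all_genes = list(all_genes)
    if not selected_snps:
        raise ValueError("no selected SNPs")
    if not focal_genes:
        raise ValueError("focal gene set is empty")
    if len(focal_genes) > len(all_genes):
        raise ValueError("focal set larger than the annotation pool")

    rng = np.random.default_rng(seed)
    mats = _distance_matrices(selected_snps, all_genes, midpoint)
    m = len(focal_genes)
    gene_index = {(g.gene_id, g.chromosome, g.start, g.end): j for j, g in enumerate(all_genes)}
    focal_cols = np.array(
        [gene_index[(g.gene_id, g.chromosome, g.start, g.end)] for g in focal_genes]
    )

    # random sets: (n_random, m) gene column indices
    if stratified:
        focal_chroms = [all_genes[c].chromosome for c in focal_cols]
        draws = np.empty((n_random, m), dtype=np.int64)
        col = 0
        for chrom in sorted(set(focal_chroms)):
            pool = np.array([j for j, g in enumerate(all_genes) if g.chromosome == chrom])
            k = sum(c == chrom for c in focal_chroms)
            for r in range(n_random):
                draws[r, col : col + k] = rng.choice(pool, size=k, replace=False)
            col += k
    else:
        n_all = len(all_genes)
        draws = np.empty((n_random, m), dtype=np.int64)
        for r in range(n_random):
            draws[r] = rng.choice(n_all, size=m, replace=False)

    def _means(col_sets):
        """Mean nearest-distance per gene-set; SNPs on chromosomes with no
        set gene are excluded from that set's mean."""
        n_sets = col_sets.shape[0]
        sums = np.zeros(n_sets)
        counts = np.zeros(n_sets)
        per_chrom_sums = {}
        for chrom, entry in mats.items():
            D = entry["D"]
            # map global gene columns -> local columns on this chromosome
            local = {c: i for i, c in enumerate(entry["cols"])}
            chrom_sums = np.full(n_sets, np.nan)
            chrom_counts = np.zeros(n_sets)
            for r in range(n_sets):
                cols = [local[c] for c in col_sets[r] if c in local]
                if not cols:
                    continue
                dmin = D[:, cols].min(axis=1)
                sums[r] += dmin.sum()
                counts[r] += len(dmin)
                chrom_sums[r] = dmin.mean()
                chrom_counts[r] = len(dmin)
            per_chrom_sums[chrom] = (chrom_sums, chrom_counts)
        with np.errstate(invalid="ignore"):
            genome_means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return genome_means, per_chrom_sums

    obs_genome, obs_chrom = _means(focal_cols[None, :])
    rand_genome, rand_chrom = _means(draws)

    def _result(chromosome, observed, randomized, n_snps):
        randomized = np.asarray(randomized, dtype=np.float64)
        delta = observed - randomized
        finite = delta[np.isfinite(delta)]
        lo, hi = (np.percentile(finite, [2.5, 97.5]) if len(finite) else (np.nan, np.nan))
        return DistanceResult(
            label=label,
            chromosome=chromosome,
            observed_mean=float(observed),
            randomized_means=randomized,
            delta=delta,
            median_delta=float(np.median(finite)) if len(finite) else float("nan"),
            ci_low=float(lo),
            ci_high=float(hi),
            n_snps=int(n_snps),
        )

    genome = _result(
        "genome", float(obs_genome[0]), rand_genome,
        sum(len(entry["D"]) for entry in mats.values()),
    )
    if not per_chromosome:
        return genome
    out = {"genome": genome}
    for chrom, (obs_s, obs_c) in obs_chrom.items():
        rand_s, _ = rand_chrom[chrom]
        if np.isfinite(obs_s[0]):
            out[chrom] = _result(chrom, float(obs_s[0]), rand_s, len(mats[chrom]["D"]))
    return out
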