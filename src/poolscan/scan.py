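"""Genome scans for selection and the empirical drift-null threshold.

Three analyses live here, all built on the stratified CMH test:

* :func:`scan` — per-site CMH between two sample groups (evolved regime
  vs. base population, or regime vs. regime), replicates as strata.
* :func:`build_drift_null` — an empirical null for "how extreme can a
  CMH p-value get from drift alone", obtained by testing replicate pairs
  *within* each regime, where no treatment contrast exists.  Its extreme
  lower quantiles (defaults 1e-5 and 1e-6, i.e. the 0.001% and 0.0001%
  percentiles) are the conservative / very-conservative significance
  thresholds applied to between-regime scans.
* :func:`overlap_bin_analysis` — binned overlap of significant SNPs
  between two regime comparisons against a randomized-p reference.

Quantiles are type-1 (inverted empirical CDF) order statistics, so a
threshold is always an element of the stored drift p-vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmh import cmh_test_many, neg_log10
from .syncio import CountMatrix

__all__ = [
    "ScanResult",
    "DriftNull",
    "scan",
    "count_above_threshold",
    "build_drift_null",
    "significant_snps",
    "overlap_bin_analysis",
    "empirical_quantile",
]


@dataclass
class ScanResult:
    """Per-SNP CMH results for one comparison (e.g. ``"C-vs-base"``)."""

    label: str
    data: pd.DataFrame  # columns: chrom, pos, statistic, p, neg_log10_p
    dropped: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "ScanResult":
        # comment="#" skips the provenance line pipeline outputs carry
        return cls(label, pd.read_csv(path, sep="\t", comment="#"))


def _harmonize(a: CountMatrix, b: CountMatrix):
    """Restrict both matrices to shared (chromosome, position) sites."""
    if a.n_sites == b.n_sites and (a.position == b.position).all() and (
        a.chromosome == b.chromosome
    ).all():
        return a, b
    key_a = pd.MultiIndex.from_arrays([a.chromosome, a.position])
    key_b = pd.MultiIndex.from_arrays([b.chromosome, b.position])
    common = key_a.intersection(key_b, sort=False)
    if len(common) == 0:
        raise ValueError("no shared sites between the two count matrices")
    mask_a = key_a.isin(common)
    mask_b = key_b.isin(common)
    return a.subset(mask_a), b.subset(mask_b)


def scan(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    pairing=None,
    *,
    continuity_correction: bool = True,
    label: str = "",
) -> ScanResult:
    """Site-wise CMH test between two sample groups, replicates as strata."""
    counts_a, counts_b = _harmonize(counts_a, counts_b)
    if pairing is None:
        if counts_a.n_replicates != counts_b.n_replicates:
            raise ValueError(
                "replicate counts differ; give an explicit pairing"
            )
        pairing = [(i + 1, i + 1) for i in range(counts_a.n_replicates)]
    ia = np.array([p[0] - 1 for p in pairing])
    ib = np.array([p[1] - 1 for p in pairing])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = cmh_test_many(
            counts_a.allele1[:, ia],
            counts_a.allele2[:, ia],
            counts_b.allele1[:, ib],
            counts_b.allele2[:, ib],
            continuity_correction=continuity_correction,
        )
    data = pd.DataFrame(
        {
            "chrom": counts_a.chromosome,
            "pos": counts_a.position,
            "statistic": stat,
            "p": p,
            "neg_log10_p": neg_log10(p),
        }
    )
    n_degenerate = int((stat == 0.0)[p >= 1.0].sum())
    return ScanResult(label, data, dropped={"degenerate_strata": n_degenerate})


def count_above_threshold(
    scan_result: ScanResult, log10_cutoff: float, by_chromosome: bool = True
) -> pd.Series:
    """Count SNPs with -log10(p) strictly above a cutoff, per chromosome + Total."""
    if scan_result.n_snps == 0:
        raise ValueError("empty scan")
    hits = scan_result.data[scan_result.data["neg_log10_p"] > log10_cutoff]
    if not by_chromosome:
        return pd.Series({"Total": len(hits)})
    counts = (
        hits.groupby("chrom").size()
        .reindex(pd.unique(scan_result.data["chrom"]), fill_value=0)
    )
    counts.loc["Total"] = counts.sum()
    return counts.astype(int)


def empirical_quantile(p_values: np.ndarray, q: float):
    """Type-1 (inverted ECDF) lower quantile of a p-value vector.

    Returns ``(threshold, low_resolution)`` where ``low_resolution`` flags
    a request below the 1/N resolution of the vector (the threshold then
    resolves to the minimum).
    """
    p_sorted = np.sort(np.asarray(p_values, dtype=np.float64))
    n = len(p_sorted)
    if n == 0:
        raise ValueError("empty p-value vector")
    low_res = q < 1.0 / n
    if low_res:
        warnings.warn(
            f"quantile {q:g} below the 1/{n} resolution; using the minimum",
            RuntimeWarning,
            stacklevel=2,
        )
    k = max(int(np.ceil(q * n)), 1)
    return float(p_sorted[k - 1]), bool(low_res)


@dataclass
class DriftNull:
    """Empirical drift-only p-value distribution and its extreme quantiles.

    ``thresholds`` maps level name -> p cutoff; by construction
    ``very_conservative <= conservative`` (order statistics at q=1e-6 and
    1e-5 of the same sorted vector).
    """

    source: str
    p_values: np.ndarray  # sorted ascending
    quantiles: dict
    thresholds: dict
    low_resolution: dict

    LEVELS = ("conservative", "very_conservative")


def build_drift_null(
    regime_counts: dict,
    replicate_pair: tuple[int, int] = (1, 2),
    *,
    pooled: bool = True,
    continuity_correction: bool = True,
    quantiles: dict | None = None,
) -> DriftNull:
    """Quantify drift by CMH tests between replicates within each regime.

    Parameters
    ----------
    regime_counts : mapping regime label -> CountMatrix (>= 2 replicates).
    replicate_pair : 1-based within-regime replicate indices to contrast
        (default the first two; other pairs give alternative nulls).
    pooled : if True (default) the regimes' replicate pairs form the K
        strata of one CMH test per site (K = number of regimes); if False,
        each regime yields its own K=1 test and the per-regime p-vectors
        are concatenated.
    quantiles : mapping level -> q; defaults to the conservative /
        very-conservative pair {1e-5, 1e-6}, i.e. the 0.001% and 0.0001%
        percentiles of the drift distribution.
    """
    if quantiles is None:
        quantiles = {"conservative": 1e-5, "very_conservative": 1e-6}
    i, j = replicate_pair
    mats = list(regime_counts.values())
    for label, m in regime_counts.items():
        if m.n_replicates < 2:
            raise ValueError(f"regime {label!r} has < 2 replicates")
        if max(i, j) > m.n_replicates:
            raise ValueError(f"replicate pair {replicate_pair} out of range for {label!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if pooled:
            maj_a = np.column_stack([m.allele1[:, i - 1] for m in mats])
            min_a = np.column_stack([m.allele2[:, i - 1] for m in mats])
            maj_b = np.column_stack([m.allele1[:, j - 1] for m in mats])
            min_b = np.column_stack([m.allele2[:, j - 1] for m in mats])
            _, p = cmh_test_many(
                maj_a, min_a, maj_b, min_b,
                continuity_correction=continuity_correction,
            )
        else:
            parts = []
            for m in mats:
                _, p_m = cmh_test_many(
                    m.allele1[:, [i - 1]], m.allele2[:, [i - 1]],
                    m.allele1[:, [j - 1]], m.allele2[:, [j - 1]],
                    continuity_correction=continuity_correction,
                )
                parts.append(p_m)
            p = np.concatenate(parts)
    p = np.sort(p)
    thresholds, low_res = {}, {}
    for level, q in quantiles.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            thresholds[level], low_res[level] = empirical_quantile(p, q)
    mode = "pooled" if pooled else "per-regime"
    return DriftNull(
        source=f"within-regime replicate pair {replicate_pair}, {mode} over "
        f"{len(regime_counts)} regimes",
        p_values=p,
        quantiles=dict(quantiles),
        thresholds=thresholds,
        low_resolution=low_res,
    )


def significant_snps(scan_result: ScanResult, null: DriftNull, level: str = "conservative"):
    """SNPs with p strictly below the drift threshold, plus a per-chromosome table."""
    if level not in null.thresholds:
        raise ValueError(f"unknown level {level!r}; have {sorted(null.thresholds)}")
    threshold = null.thresholds[level]
    hits = scan_result.data[scan_result.data["p"] < threshold]
    counts = (
        hits.groupby("chrom").size()
        .reindex(pd.unique(scan_result.data["chrom"]), fill_value=0)
    )
    counts.loc["Total"] = counts.sum()
    return hits, counts.astype(int)


def overlap_bin_analysis(
    scan_a: ScanResult,
    scan_b: ScanResult,
    sig_b,
    n_bins: int = 30,
    n_randomizations: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binned overlap of one scan's significance with another's significant set.

    SNPs shared by both scans are placed in ``n_bins`` equal-width bins of
    -log10(p) in scan a; per bin the observed proportion of SNPs that are
    significant in scan b is compared with the proportions obtained after
    shuffling scan b's significance labels across SNPs (the randomized-p
    reference; under independent evolution the observed proportion should
    be flat across bins and match the reference).

    ``sig_b`` is a set of ``(chrom, pos)`` pairs (or a DataFrame with those
    columns) marking scan b's significant SNPs.

    Returns a DataFrame with, per bin: edges, SNP count, observed
    proportion (NaN where the bin is empty), and the mean and 2.5/97.5
    percentile envelope of the randomized proportions.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if isinstance(sig_b, pd.DataFrame):
        sig_b = set(zip(sig_b["chrom"], sig_b["pos"]))
    merged = scan_a.data.merge(
        scan_b.data[["chrom", "pos"]], on=["chrom", "pos"], how="inner"
    )
    if merged.empty:
        raise ValueError("scans share no SNPs")
    x = merged["neg_log10_p"].to_numpy()
    member = np.array(
        [(c, p) in sig_b for c, p in zip(merged["chrom"], merged["pos"])]
    )
    edges = np.linspace(0.0, x.max(), n_bins + 1)
    bin_idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    n_per_bin = np.bincount(bin_idx, minlength=n_bins)
    obs_hits = np.bincount(bin_idx, weights=member, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        observed = np.where(n_per_bin > 0, obs_hits / np.maximum(n_per_bin, 1), np.nan)

    rng = np.random.default_rng(seed)
    rand_props = np.empty((n_randomizations, n_bins))
    shuffled = member.copy()
    for r in range(n_randomizations):
        rng.shuffle(shuffled)
        hits = np.bincount(bin_idx, weights=shuffled, minlength=n_bins)
        rand_props[r] = np.where(n_per_bin > 0, hits / np.maximum(n_per_bin, 1), np.nan)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rand_mean = np.nanmean(rand_props, axis=0)
        rand_lo = np.nanpercentile(rand_props, 2.5, axis=0)
        rand_hi = np.nanpercentile(rand_props, 97.5, axis=0)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "left": edges[:-1],
            "right": edges[1:],
            "n_snps": n_per_bin,
            "observed_proportion": observed,
            "randomized_mean": rand_mean,
            "randomized_lo": rand_lo,
            "randomized_hi": rand_hi,
        }
    )
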