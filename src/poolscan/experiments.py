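"""Calibration and recovery experiments under the modeled study conditions.

Each function runs one self-contained validation experiment on synthetic
data generated by :mod:`poolscan.simulate` and returns plain numbers:

* agreement of the CMH statistic with an independent reference
  implementation on random stratified tables;
* calibration of the empirical drift null (uniformity of drift-only
  p-values; pass fraction of the conservative threshold by construction);
* recovery of planted selected loci (ranking and regime count ordering);
* coverage of the Δdistance 95% interval under a random focal set;
* flatness of the randomized-p overlap reference across significance bins.

The default problem sizes are the study conditions themselves (10,000
polymorphic sites, Ne = 500, 20 generations, 3 regimes x 3 replicates,
coverage 40, 5% selected loci at s = 0.1 in the UF regime).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cmh import StratifiedTable, cmh_test, cmh_test_many
from .proximity import delta_distance_test
from .scan import build_drift_null, overlap_bin_analysis, scan, significant_snps
from .simulate import SimConfig, simulate_annotation, simulate_experiment

__all__ = [
    "cmh_reference_agreement",
    "drift_null_calibration",
    "selection_recovery",
    "proximity_null_coverage",
    "overlap_reference_flatness",
]


def cmh_reference_agreement(n_tables: int = 1000, k: int = 3, seed: int = 0) -> float:
    """Maximum relative error of the CMH statistic vs. statsmodels.

    Random 2x2xK tables with cells in [1, 100); the reference is
    ``statsmodels.stats.contingency_tables.StratifiedTable``, an
    implementation independent of this package.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable as SMTable

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        t = rng.integers(1, 100, size=(k, 2, 2))
        mine = cmh_test(StratifiedTable(t), continuity_correction=False)
        ref = SMTable(t.transpose(1, 2, 0).astype(float)).test_null_odds(
            correction=False
        )
        worst = max(
            worst, abs(mine.statistic - ref.statistic) / max(abs(ref.statistic), 1e-12)
        )
    return float(worst)


def _drift_only_experiment(seed: int, n_sites: int = 10_000):
    config = SimConfig(
        n_sites=n_sites,
        effective_size=500,
        generations=20,
        coverage=40.0,
        selected_fraction=0.0,
        seed=seed,
    )
    experiment = simulate_experiment(config)
    return experiment.subset(experiment.polymorphic_mask())


def drift_null_calibration(seed: int = 0, n_sites: int = 10_000) -> dict:
    """Drift-only simulation: p-value uniformity and threshold calibration.

    Returns the KS distance of the drift-pair CMH p-values from the
    uniform distribution, and the fraction of a drift-only between-regime
    scan passing the conservative (q = 1e-5) drift threshold.  Note that
    drift between replicate pools adds extra-binomial variance, so the
    drift p-value distribution is *not* expected to be exactly uniform —
    that excess is precisely what the empirical threshold absorbs.
    """
    experiment = _drift_only_experiment(seed, n_sites)
    mats = {r: experiment.count_matrix(r) for r in experiment.config.regimes}
    null = build_drift_null(mats)
    ks = stats.kstest(null.p_values, "uniform").statistic

    between = scan(mats["C"], mats["PF"], label="C-vs-PF")
    hits, _ = significant_snps(between, null, "conservative")
    return {
        "ks_distance": float(ks),
        "pass_fraction": len(hits) / between.n_snps,
        "n_sites": int(between.n_snps),
        "conservative_threshold": float(null.thresholds["conservative"]),
    }


def selection_recovery(seed: int = 0, n_sites: int = 10_000) -> dict:
    """Planted-selection recovery: ranking of true loci and count ordering.

    5% of sites evolve at s = 0.1 in the UF regime.  Reports the fraction
    of truly selected sites ranking in the top 5% of the UF-vs-base scan,
    the median rank quantile of true loci, and drift-thresholded
    significant-SNP counts for the three between-regime comparisons.
    """
    config = SimConfig(n_sites=n_sites, seed=seed)
    experiment = simulate_experiment(config)
    experiment = experiment.subset(experiment.polymorphic_mask())

    base = experiment.count_matrix("base")
    mats = {r: experiment.count_matrix(r) for r in config.regimes}
    result = scan(mats["UF"], base, label="UF-vs-base")
    p = result.data["p"].to_numpy()
    order = np.argsort(p, kind="stable")
    rank = np.empty(len(p))
    rank[order] = np.arange(len(p))
    sel = experiment.truth.selected[:, list(config.regimes).index("UF")]
    top5 = rank[sel] < 0.05 * len(p)

    null = build_drift_null(mats)
    counts = {}
    for a, b in [("C", "PF"), ("C", "UF"), ("PF", "UF")]:
        between = scan(mats[a], mats[b], label=f"{a}-vs-{b}")
        _, table = significant_snps(between, null, "conservative")
        counts[f"{a}-vs-{b}"] = int(table["Total"])
    return {
        "top5_fraction": float(top5.mean()),
        "median_rank_quantile": float(np.median(rank[sel]) / len(p)),
        "n_selected": int(sel.sum()),
        "significant_counts": counts,
        "ordering_matches_truth": counts["C-vs-UF"] > counts["C-vs-PF"]
        and counts["PF-vs-UF"] > counts["C-vs-PF"],
    }


def proximity_null_coverage(
    seed: int = 0,
    n_repetitions: int = 100,
    n_random: int = 300,
    n_genes: int = 400,
    focal_size: int = 34,
    n_snps: int = 40,
) -> float:
    """Fraction of random-focal-set fixtures whose Δ 95% interval straddles 0.

    Under exchangeability this coverage is ~95%; each repetition draws a
    fresh focal gene set at random while the SNP set stays fixed.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(n_sites=10, seed=int(rng.integers(2**31)))
    genes = simulate_annotation(config, rng=rng, n_genes=n_genes)
    chrom_names = config.chromosome_names()
    snps = [
        (
            chrom_names[int(rng.integers(len(chrom_names)))],
            int(rng.integers(1, config.chromosome_length)),
        )
        for _ in range(n_snps)
    ]
    straddle = 0
    for _ in range(n_repetitions):
        idx = rng.choice(n_genes, size=focal_size, replace=False)
        focal = [genes[i] for i in idx]
        result = delta_distance_test(
            snps, focal, genes, n_random=n_random, seed=int(rng.integers(2**31))
        )
        straddle += not result.excludes_zero
    return straddle / n_repetitions


def overlap_reference_flatness(seed: int = 0, n_sites: int = 10_000, n_bins: int = 30) -> dict:
    """Slope of the randomized-p overlap reference across significance bins.

    On drift-only scans the reference proportions should be independent of
    the bin (flat at |sig_b|/N); returns the OLS slope of the randomized
    mean proportion on the bin midpoint and its p-value.
    """
    experiment = _drift_only_experiment(seed, n_sites)
    mats = {r: experiment.count_matrix(r) for r in experiment.config.regimes}
    scan_a = scan(mats["C"], mats["PF"], label="C-vs-PF")
    scan_b = scan(mats["C"], mats["UF"], label="C-vs-UF")
    sig = scan_b.data.nsmallest(max(int(0.05 * scan_b.n_snps), 1), "p")
    bins = overlap_bin_analysis(
        scan_a, scan_b, sig, n_bins=n_bins, n_randomizations=500, seed=seed
    )
    filled = bins.dropna(subset=["randomized_mean"])
    fit = stats.linregress(
        (filled["left"] + filled["right"]) / 2, filled["randomized_mean"]
    )
    return {
        "slope": float(fit.slope),
        "slope_p_value": float(fit.pvalue),
        "n_bins_nonempty": int(len(filled)),
        "marginal_rate": len(sig) / scan_b.n_snps,
    }
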