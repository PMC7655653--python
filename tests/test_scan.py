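"""Selection scans, drift-null thresholds, and the overlap binning."""

import numpy as np
import pandas as pd
import pytest

from poolscan.scan import (
    DriftNull,
    ScanResult,
    build_drift_null,
    count_above_threshold,
    empirical_quantile,
    overlap_bin_analysis,
    scan,
    significant_snps,
)
from poolscan.syncio import CountMatrix

pytestmark = pytest.mark.filterwarnings(
    "ignore:all strata degenerate:RuntimeWarning"
)


def _matrix(allele1, allele2, chrom=None, pos=None):
    allele1 = np.asarray(allele1)
    n = allele1.shape[0]
    return CountMatrix(
        np.asarray(chrom if chrom is not None else ["2L"] * n, dtype=object),
        np.asarray(pos if pos is not None else np.arange(1, n + 1)),
        allele1,
        np.asarray(allele2),
    )


def _fake_scan(p_values, chrom=None, label="x"):
    p = np.asarray(p_values, dtype=float)
    return ScanResult(
        label,
        pd.DataFrame(
            {
                "chrom": chrom if chrom is not None else ["2L"] * len(p),
                "pos": np.arange(1, len(p) + 1),
                "statistic": np.zeros(len(p)),
                "p": p,
                "neg_log10_p": -np.log10(p),
            }
        ),
    )


class TestScan:
    def test_identical_inputs_give_p_one_everywhere(self, rng):
        a1 = rng.integers(10, 40, size=(50, 3))
        a2 = rng.integers(10, 40, size=(50, 3))
        mat = _matrix(a1, a2)
        result = scan(mat, mat, continuity_correction=False)
        assert (result.data["p"] == 1.0).all()

    def test_zero_shared_sites_is_an_error(self, rng):
        a = _matrix([[10, 10]], [[5, 5]], chrom=["2L"], pos=[1])
        b = _matrix([[10, 10]], [[5, 5]], chrom=["3R"], pos=[9])
        with pytest.raises(ValueError, match="no shared sites"):
            scan(a, b)

    def test_harmonization_intersects_sites(self, rng):
        a1 = rng.integers(10, 40, size=(5, 2))
        a = _matrix(a1, a1, pos=[1, 2, 3, 4, 5])
        b = _matrix(a1, a1, pos=[3, 4, 5, 6, 7])
        result = scan(a, b)
        assert list(result.data["pos"]) == [3, 4, 5]

    def test_selected_sites_rank_near_the_top(self, selection_experiment):
        exp = selection_experiment
        result = scan(exp.count_matrix("UF"), exp.count_matrix("base"))
        order = np.argsort(result.data["p"].to_numpy())
        rank = np.empty(len(order))
        rank[order] = np.arange(len(order))
        sel = exp.truth.selected[:, list(exp.truth.regimes).index("UF")]
        median_rank = np.median(rank[sel])
        assert median_rank < 0.1 * len(rank)  # median in the top decile


class TestCountAboveThreshold:
    def test_strict_inequality_at_the_cutoff(self):
        result = _fake_scan([1e-8, 1e-6])
        counts = count_above_threshold(result, 7.0)
        assert counts["Total"] == 1

    def test_zero_cutoff_counts_every_p_below_one(self):
        result = _fake_scan([0.5, 1.0, 1e-3])
        assert count_above_threshold(result, 0.0)["Total"] == 2

    def test_infinite_cutoff_counts_nothing(self):
        result = _fake_scan([1e-300])
        assert count_above_threshold(result, np.inf)["Total"] == 0

    def test_counts_split_by_chromosome(self):
        result = _fake_scan([1e-8, 1e-8, 0.5], chrom=["2L", "3R", "3R"])
        counts = count_above_threshold(result, 7.0)
        assert counts["2L"] == 1 and counts["3R"] == 1 and counts["Total"] == 2


class TestEmpiricalQuantile:
    def test_exact_uniform_grid(self):
        grid = np.arange(1, 10**6 + 1) / 10**6
        threshold, low_res = empirical_quantile(grid, 1e-5)
        assert not low_res
        assert threshold == pytest.approx(1e-5, rel=0.2)

    def test_below_resolution_resolves_to_minimum_with_warning(self):
        with pytest.warns(RuntimeWarning, match="resolution"):
            threshold, low_res = empirical_quantile(np.linspace(0.1, 1, 10), 1e-5)
        assert low_res and threshold == pytest.approx(0.1)


class TestDriftNull:
    def test_thresholds_are_nested_order_statistics(self, drift_experiment):
        mats = {r: drift_experiment.count_matrix(r) for r in ("C", "PF", "UF")}
        null = build_drift_null(mats)
        assert null.thresholds["very_conservative"] <= null.thresholds["conservative"]
        assert null.thresholds["conservative"] in null.p_values

    def test_alternative_replicate_pairs_give_alternative_nulls(self, drift_experiment):
        mats = {r: drift_experiment.count_matrix(r) for r in ("C", "PF", "UF")}
        a = build_drift_null(mats, replicate_pair=(1, 2))
        b = build_drift_null(mats, replicate_pair=(2, 3))
        assert a.source != b.source
        assert not np.array_equal(a.p_values, b.p_values)

    def test_per_regime_mode_concatenates_three_nulls(self, drift_experiment):
        mats = {r: drift_experiment.count_matrix(r) for r in ("C", "PF", "UF")}
        pooled = build_drift_null(mats, pooled=True)
        split = build_drift_null(mats, pooled=False)
        assert len(split.p_values) == 3 * len(pooled.p_values)

    def test_too_few_replicates_rejected(self, drift_experiment):
        mat = drift_experiment.count_matrix("C")
        single = CountMatrix(
            mat.chromosome, mat.position, mat.allele1[:, :1], mat.allele2[:, :1]
        )
        with pytest.raises(ValueError, match="2 replicates"):
            build_drift_null({"C": single})

    def test_calibration_by_construction(self, rng):
        # applying a threshold back to its own source selects floor/ceil(qN)
        p = np.sort(rng.uniform(size=350_000))
        q = 1e-5  # qN = 3.5
        threshold, _ = empirical_quantile(p, q)
        n_below = int((p < threshold).sum())
        assert n_below in (3, 4)


class TestSignificantSnps:
    def _null(self, thresholds):
        return DriftNull("fake", np.array([]), {}, thresholds, {})

    def test_threshold_below_minimum_selects_nothing(self):
        result = _fake_scan([0.5, 0.2])
        hits, counts = significant_snps(result, self._null({"conservative": 0.1}))
        assert len(hits) == 0 and counts["Total"] == 0

    def test_threshold_above_maximum_selects_everything(self):
        result = _fake_scan([0.5, 0.2])
        hits, _ = significant_snps(result, self._null({"conservative": 0.9}))
        assert len(hits) == 2

    def test_very_conservative_set_is_nested_in_conservative(self, drift_experiment):
        mats = {r: drift_experiment.count_matrix(r) for r in ("C", "PF", "UF")}
        null = build_drift_null(mats)
        result = scan(mats["C"], mats["PF"])
        strict, _ = significant_snps(result, null, "very_conservative")
        loose, _ = significant_snps(result, null, "conservative")
        strict_set = set(zip(strict["chrom"], strict["pos"]))
        loose_set = set(zip(loose["chrom"], loose["pos"]))
        assert strict_set <= loose_set


class TestOverlap:
    def test_full_reference_set_gives_proportion_one(self, rng):
        p = rng.uniform(size=300)
        a, b = _fake_scan(p, label="a"), _fake_scan(rng.uniform(size=300), label="b")
        sig_b = set(zip(b.data["chrom"], b.data["pos"]))
        bins = overlap_bin_analysis(a, b, sig_b, n_bins=5, n_randomizations=10, seed=0)
        filled = bins.dropna(subset=["observed_proportion"])
        assert (filled["observed_proportion"] == 1.0).all()

    def test_randomized_reference_is_flat_at_the_marginal_rate(self, rng):
        p = rng.uniform(size=2000)
        a = _fake_scan(p, label="a")
        b = _fake_scan(rng.uniform(size=2000), label="b")
        sig = b.data.nsmallest(200, "p")
        sig_b = set(zip(sig["chrom"], sig["pos"]))
        bins = overlap_bin_analysis(a, b, sig_b, n_bins=8, n_randomizations=400, seed=1)
        filled = bins.dropna(subset=["randomized_mean"])
        # every bin's randomized mean is near |sig_b|/N = 0.1, independent of bin
        assert np.allclose(filled["randomized_mean"], 0.1, atol=0.05)

    def test_constructed_top_bin_overlap(self):
        # 90 null SNPs and 10 extreme SNPs; the reference set is exactly
        # those 10, so the top bin hits proportion 1 and the rest 0
        p = np.concatenate([np.full(90, 0.5), np.full(10, 1e-10)])
        a = _fake_scan(p, label="a")
        b = _fake_scan(p, label="b")
        sig_b = set(zip(b.data["chrom"][90:], b.data["pos"][90:]))
        bins = overlap_bin_analysis(a, b, sig_b, n_bins=10, n_randomizations=5, seed=0)
        filled = bins.dropna(subset=["observed_proportion"])
        assert filled.iloc[-1]["observed_proportion"] == 1.0
        assert (filled.iloc[:-1]["observed_proportion"] == 0.0).all()
        # empty bins are reported as missing, not zero
        assert bins["observed_proportion"].isna().sum() == 8

    def test_requires_at_least_two_bins(self):
        a = _fake_scan([0.5])
        with pytest.raises(ValueError, match="n_bins"):
            overlap_bin_analysis(a, a, set(), n_bins=1)


def test_uf_regime_with_planted_selection_yields_most_significant_snps(
    selection_experiment,
):
    """The qualitative ordering: comparisons involving the regime with
    planted selection carry more significant SNPs than the drift-only pair."""
    exp = selection_experiment
    mats = {r: exp.count_matrix(r) for r in ("C", "PF", "UF")}
    null = build_drift_null(mats)
    totals = {}
    for a, b in [("C", "PF"), ("C", "UF"), ("PF", "UF")]:
        result = scan(mats[a], mats[b])
        _, counts = significant_snps(result, null, "conservative")
        totals[(a, b)] = counts["Total"]
    assert totals[("C", "UF")] > totals[("C", "PF")]
    assert totals[("PF", "UF")] > totals[("C", "PF")]
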