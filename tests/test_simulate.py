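"""The Wright–Fisher synthetic-data generator against closed-form oracles."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from poolscan.cmh import cmh_test_many
from poolscan.simulate import (
    ConfigError,
    SimConfig,
    TruthTable,
    evolve_replicates,
    pick_responsive_genes,
    sample_pool_counts,
    simulate_annotation,
    simulate_base_frequencies,
    simulate_experiment,
    simulate_proteome,
)


def _truth(config, base, s=0.0, selected=None):
    n = len(base)
    k = len(config.regimes)
    sel = np.zeros((n, k), dtype=bool)
    sval = np.zeros((n, k))
    if selected is not None:
        sel[selected] = True
        sval[selected] = s
    return TruthTable(tuple(config.regimes), base, sel, sval)


class TestBaseFrequencies:
    def test_frequencies_are_strictly_polymorphic(self):
        config = SimConfig(n_sites=1000, seed=3)
        freqs = simulate_base_frequencies(config)
        assert len(freqs) == 1000
        assert ((freqs > 0) & (freqs < 1)).all()

    def test_point_mass_spectrum(self):
        config = SimConfig(n_sites=50, base_freq_distribution=("point", 0.5))
        assert (simulate_base_frequencies(config) == 0.5).all()

    def test_beta_sample_mean_matches_closed_form(self):
        # Beta(2,2): mean 1/2, var 1/20; 3 SE band at n=10000
        config = SimConfig(n_sites=10_000, base_freq_distribution=("beta", 2, 2), seed=5)
        freqs = simulate_base_frequencies(config)
        se = np.sqrt((1 / 20) / 10_000)
        assert abs(freqs.mean() - 0.5) < 3 * se

    @pytest.mark.parametrize(
        "dist", [("beta", -1, 2), ("point", 0.0), ("uniform", 0.9, 0.1), ("gauss", 1)]
    )
    def test_invalid_spectra_raise_config_errors(self, dist):
        with pytest.raises(ConfigError):
            simulate_base_frequencies(SimConfig(n_sites=10, base_freq_distribution=dist))


class TestEvolve:
    def test_drift_vanishes_at_very_large_population_size(self):
        config = SimConfig(
            n_sites=500, effective_size=10_000_000, regimes=("C",), n_replicates=1, seed=2
        )
        base = simulate_base_frequencies(config)
        truth = _truth(config, base)
        final = evolve_replicates(base, truth, config)["C"][:, 0]
        assert np.max(np.abs(final - base)) < 0.01

    def test_neutral_variance_matches_wright_fisher_formula(self):
        # Var(p_t) = p0 q0 [1 - (1 - 1/2Ne)^t]
        config = SimConfig(
            n_sites=10_000,
            effective_size=500,
            base_freq_distribution=("point", 0.5),
            regimes=("C",),
            n_replicates=1,
            seed=4,
        )
        base = simulate_base_frequencies(config)
        truth = _truth(config, base)
        final = evolve_replicates(base, truth, config)["C"][:, 0]
        expected = 0.25 * (1 - (1 - 1 / 1000) ** 20)
        assert final.var() == pytest.approx(expected, rel=0.1)

    def test_selection_matches_deterministic_recursion_without_drift(self):
        config = SimConfig(
            n_sites=100,
            effective_size=10_000_000,
            base_freq_distribution=("point", 0.5),
            regimes=("UF",),
            selected_regimes=("UF",),
            n_replicates=1,
            seed=6,
        )
        base = simulate_base_frequencies(config)
        truth = _truth(config, base, s=0.5, selected=slice(None))
        final = evolve_replicates(base, truth, config)["UF"][:, 0]
        p = 0.5
        for _ in range(20):  # iterate p' = p(1+s)/(1+sp) by hand
            p = p * 1.5 / (1 + 0.5 * p)
        assert np.allclose(final, p, atol=0.01)

    def test_fixation_is_absorbing_at_small_population_size(self):
        config = SimConfig(
            n_sites=300, effective_size=5, generations=200,
            regimes=("C",), n_replicates=1, seed=8,
        )
        base = simulate_base_frequencies(config)
        final = evolve_replicates(base, _truth(config, base), config)["C"][:, 0]
        # after 200 generations at 2Ne=10 essentially everything has fixed,
        # and fixed frequencies are exactly 0 or 1 (never re-polymorphic)
        assert np.isin(final, [0.0, 1.0]).mean() > 0.99

    def test_replicates_are_independent_but_reproducible(self):
        config = SimConfig(n_sites=200, regimes=("C",), n_replicates=2, seed=9)
        base = simulate_base_frequencies(config)
        a = evolve_replicates(base, _truth(config, base), config)["C"]
        b = evolve_replicates(base, _truth(config, base), config)["C"]
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a[:, 0], a[:, 1])


class TestPoolCounts:
    def test_fixed_frequencies_give_one_sided_counts(self, rng):
        zero = sample_pool_counts(np.zeros(100), 40, rng)
        assert (zero[:, 1] == 0).all()  # no alternate reads
        one = sample_pool_counts(np.ones(100), 40, rng)
        assert (one[:, 0] == 0).all()  # no reference reads

    def test_binomial_mean_at_half_frequency(self, rng):
        counts = sample_pool_counts(np.full(20_000, 0.5), 40, rng, fixed_depth=True)
        assert (counts.sum(axis=1) == 40).all()
        se = np.sqrt(40 * 0.25 / 20_000)
        assert abs(counts[:, 1].mean() - 20) < 3 * se

    def test_non_positive_coverage_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_pool_counts(np.array([0.5]), 0, rng)


class TestAnnotation:
    def test_intervals_stay_within_chromosomes(self):
        config = SimConfig(n_sites=10, chromosome_length=50_000, seed=1)
        genes = simulate_annotation(config, max_length=4000)
        assert all(1 <= g.start <= g.end <= 50_000 for g in genes)

    def test_genes_longer_than_chromosome_rejected(self):
        config = SimConfig(n_sites=10, chromosome_length=1000)
        with pytest.raises(ConfigError):
            simulate_annotation(config, max_length=1000)

    def test_responsive_picks(self, rng):
        config = SimConfig(n_sites=10, seed=1)
        genes = simulate_annotation(config, n_genes=20)
        assert pick_responsive_genes(genes, 0) == []
        assert set(pick_responsive_genes(genes, 20)) == {g.gene_id for g in genes}
        with pytest.raises(ValueError):
            pick_responsive_genes(genes, 21)
        a = pick_responsive_genes(genes, 5, rng=np.random.default_rng(3))
        b = pick_responsive_genes(genes, 5, rng=np.random.default_rng(3))
        assert a == b


class TestProteomeSim:
    def test_no_missingness_means_full_detection(self):
        from poolscan.proteome import detection_filter

        table, _ = simulate_proteome(n_proteins=50, missing_rate=0.0, seed=1)
        filtered, audit = detection_filter(table)
        assert audit["retained"] == 50

    def test_strong_effects_are_always_detected(self):
        from poolscan.proteome import pairwise_contrast, significant_sets

        table, responsive = simulate_proteome(
            n_proteins=100, n_responsive=10, effect_size=5.0, noise_sd=1.0,
            missing_rate=0.0, seed=2,
        )
        contrasts = pairwise_contrast(table, "UF", "C")
        sets = significant_sets(contrasts, alpha=0.05)
        assert set(responsive) <= sets["sets"]["UF-C"]

    def test_null_omnibus_rejects_at_nominal_rate(self):
        from poolscan.proteome import omnibus_test

        table, _ = simulate_proteome(
            n_proteins=2000, n_responsive=0, effect_size=0.0, missing_rate=0.0, seed=3
        )
        p = omnibus_test(table)
        rate = (p <= 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)


class TestExperiment:
    def test_identical_configs_give_byte_identical_sync(self, tmp_path):
        config = SimConfig(n_sites=200, seed=42)
        a, b = tmp_path / "a.sync", tmp_path / "b.sync"
        simulate_experiment(config).write_sync(a)
        simulate_experiment(config).write_sync(b)
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.filterwarnings("ignore:all strata degenerate:RuntimeWarning")
    def test_drift_pair_and_cross_regime_p_values_match_in_distribution(
        self, drift_experiment
    ):
        """With s = 0 everywhere, allele-frequency change between replicates
        of one regime is distributed like change between regimes."""
        c = drift_experiment.count_matrix("C")
        pf = drift_experiment.count_matrix("PF")
        _, p_within = cmh_test_many(
            c.allele1[:, [0]], c.allele2[:, [0]], c.allele1[:, [1]], c.allele2[:, [1]]
        )
        _, p_between = cmh_test_many(
            c.allele1[:, [0]], c.allele2[:, [0]], pf.allele1[:, [0]], pf.allele2[:, [0]]
        )
        assert ks_2samp(p_within, p_between).pvalue > 1e-3

    def test_truth_table_marks_neutral_sites_with_zero_s(self, selection_experiment):
        truth = selection_experiment.truth
        assert (truth.s[~truth.selected] == 0).all()
        assert (truth.s[truth.selected] == 0.1).all()
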