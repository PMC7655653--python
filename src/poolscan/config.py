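"""Run configuration, validation, provenance, and end-to-end orchestration.

:class:`RunConfig` gathers every tunable of the pipeline with defaults set
to the modeled study's stated values where one exists (target coverage 40,
Manhattan counting cutoff -log10(p) > 7, drift quantiles 1e-5 / 1e-6, 30
overlap bins, 10,000 random gene sets, min 20 SNPs per gene, alpha 0.05,
3 replicates).  :func:`run_pipeline` executes the whole analysis on a
synthetic experiment: divergence-from-base scans, between-regime scans
with the empirical drift threshold, overlap binning, gene-wise scores,
the Δdistance test, and the proteome contrast pipeline, emitting TSVs and
one machine-readable JSON summary.  All outputs carry the configuration
hash; runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cmh import cmh_test_many, neg_log10
from .genewise import (
    assign_snps_to_genes,
    gene_drift_threshold,
    gene_mean_p,
    scores_to_frame,
    significant_genes,
    write_bed,
)
from .proteome import (
    detection_filter,
    omnibus_test,
    pairwise_contrast,
    significant_sets,
)
from .proximity import delta_distance_test
from .scan import (
    ScanResult,
    build_drift_null,
    count_above_threshold,
    overlap_bin_analysis,
    scan,
    significant_snps,
)
from .simulate import (
    SimConfig,
    pick_responsive_genes,
    simulate_annotation,
    simulate_experiment,
    simulate_proteome,
)

__all__ = ["RunConfig", "ConfigValidationError", "run_pipeline"]


class ConfigValidationError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n- " + "\n- ".join(self.problems))


@dataclass
class RunConfig:
    """All pipeline tunables plus provenance."""

    outdir: str = "poolscan_out"
    seed: int = 0
    # sync normalization
    target_coverage: int = 40
    max_coverage: int = 10_000
    min_minor_count: int = 2
    # scan / thresholds
    log10_cutoff: float = 7.0
    q_conservative: float = 1e-5
    q_very_conservative: float = 1e-6
    continuity_correction: bool = True
    pooled_null: bool = True
    per_chromosome_thresholds: bool = False
    drift_pair: tuple[int, int] = (1, 2)
    # overlap
    n_bins: int = 30
    n_randomizations: int = 100
    # gene-wise
    min_snps: int = 20
    gene_q: float = 1e-5
    # proximity
    n_random: int = 10_000
    n_responsive_proteins: int = 34
    n_responsive_transcripts: int = 204
    # proteome
    alpha: float = 0.05
    min_reps: int = 2
    proteome: dict = field(default_factory=dict)  # simulate_proteome overrides
    # simulation
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def validate(self) -> None:
        problems = []
        if self.target_coverage < 1:
            problems.append("target_coverage must be >= 1")
        if self.max_coverage < self.target_coverage:
            problems.append("max_coverage must be >= target_coverage")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        for key in ("q_conservative", "q_very_conservative", "gene_q"):
            if not 0 < getattr(self, key) < 1:
                problems.append(f"{key} must be in (0, 1)")
        if self.q_very_conservative > self.q_conservative:
            problems.append("q_very_conservative must be <= q_conservative")
        if self.n_bins < 2:
            problems.append("n_bins must be >= 2")
        if self.n_random < 1 or self.n_randomizations < 1:
            problems.append("randomization counts must be >= 1")
        if self.min_snps < 1:
            problems.append("min_snps must be >= 1")
        if self.per_chromosome_thresholds and not self.pooled_null:
            problems.append(
                "per_chromosome_thresholds and pooled_null=False conflict: "
                "per-chromosome thresholds require the pooled drift null "
                "(keys: per_chromosome_thresholds, pooled_null)"
            )
        if problems:
            raise ConfigValidationError(problems)

    def sim_config(self) -> SimConfig:
        params = {"seed": self.seed, "coverage": float(self.target_coverage)}
        params.update(self.simulate)
        if "regimes" in params:
            params["regimes"] = tuple(params["regimes"])
        if "selected_regimes" in params:
            params["selected_regimes"] = tuple(params["selected_regimes"])
        return SimConfig(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_pair"] = list(self.drift_pair)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigValidationError([f"unknown key {k!r}" for k in sorted(unknown)])
        if "drift_pair" in data:
            data["drift_pair"] = tuple(data["drift_pair"])
        return cls(**data)


def _write_tsv(df, path, config_hash: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# poolscan {__version__} config_hash={config_hash}\n")
        df.to_csv(handle, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage on a synthetic experiment.

    Returns the summary dict (also written to ``<outdir>/summary.json``)
    shaped like the study's result tables: per-chromosome SNP counts for
    the divergence-from-base scans, drift-thresholded counts for the
    between-regime scans, gene-wise significant genes, Δdistance
    intervals, and proteome contrast set sizes.
    """
    config.validate()
    chash = config.config_hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    sim_config = config.sim_config()
    experiment = simulate_experiment(sim_config)
    experiment = experiment.subset(experiment.polymorphic_mask(config.min_minor_count))
    experiment.write_sync(outdir / "simulated.sync")

    summary = {
        "poolscan_version": __version__,
        "config_hash": chash,
        "config": config.to_dict(),
        "n_polymorphic_sites": int(experiment.count_matrix("base").n_sites),
    }

    base = experiment.count_matrix("base")
    regimes = list(sim_config.regimes)
    regime_mats = {r: experiment.count_matrix(r) for r in regimes}

    # divergence from base, counted at the fixed -log10(p) cutoff
    vs_base = {}
    summary["vs_base_counts"] = {}
    for regime in regimes:
        result = scan(
            regime_mats[regime], base,
            continuity_correction=config.continuity_correction,
            label=f"{regime}-vs-base",
        )
        vs_base[regime] = result
        _write_tsv(result.data, outdir / f"scan_{regime}_vs_base.tsv", chash)
        summary["vs_base_counts"][regime] = count_above_threshold(
            result, config.log10_cutoff
        ).to_dict()

    # between-regime scans with the empirical drift thresholds
    null = build_drift_null(
        regime_mats,
        replicate_pair=config.drift_pair,
        pooled=config.pooled_null,
        continuity_correction=config.continuity_correction,
        quantiles={
            "conservative": config.q_conservative,
            "very_conservative": config.q_very_conservative,
        },
    )
    summary["drift_null"] = {
        "source": null.source,
        "n": int(len(null.p_values)),
        "thresholds": {k: float(v) for k, v in null.thresholds.items()},
    }
    pair_scans = {}
    summary["between_regime_counts"] = {}
    sig_sets = {}
    for a, b in combinations(regimes, 2):
        label = f"{a}-vs-{b}"
        result = scan(
            regime_mats[a], regime_mats[b],
            continuity_correction=config.continuity_correction,
            label=label,
        )
        pair_scans[(a, b)] = result
        _write_tsv(result.data, outdir / f"scan_{a}_vs_{b}.tsv", chash)
        counts = {}
        for level in ("conservative", "very_conservative"):
            hits, table = significant_snps(result, null, level)
            counts[level] = table.to_dict()
            if level == "conservative":
                sig_sets[(a, b)] = hits
                _write_tsv(hits, outdir / f"significant_{a}_vs_{b}.tsv", chash)
        summary["between_regime_counts"][label] = counts

    # pairwise overlap binning against the randomized-p reference
    summary["overlap"] = {}
    for (a, b), result in pair_scans.items():
        other = next(k for k in pair_scans if k != (a, b))
        bins = overlap_bin_analysis(
            result,
            pair_scans[other],
            sig_sets[other],
            n_bins=config.n_bins,
            n_randomizations=config.n_randomizations,
            seed=int(rng.integers(2**31)),
        )
        _write_tsv(bins, outdir / f"overlap_{result.label}.tsv", chash)
        summary["overlap"][result.label] = {
            "reference": pair_scans[other].label,
            "n_bins_nonempty": int(bins["observed_proportion"].notna().sum()),
        }

    # gene-wise aggregation with the gene-level drift threshold
    annotation = simulate_annotation(sim_config, rng=np.random.default_rng(config.seed + 1))
    write_bed(annotation, outdir / "annotation.bed")
    drift_scan = _drift_scan(regime_mats, config)
    drift_scores = gene_mean_p(
        assign_snps_to_genes(drift_scan, annotation), min_snps=config.min_snps
    )
    summary["genewise"] = {}
    if drift_scores:
        threshold = gene_drift_threshold(drift_scores, q=config.gene_q)
        summary["genewise"]["drift_threshold"] = float(threshold)
        summary["genewise"]["n_drift_genes"] = len(drift_scores)
        for (a, b), result in pair_scans.items():
            scores = gene_mean_p(
                assign_snps_to_genes(result, annotation), min_snps=config.min_snps
            )
            frame = scores_to_frame(scores)
            _write_tsv(frame, outdir / f"genewise_{a}_vs_{b}.tsv", chash)
            summary["genewise"][f"{a}-vs-{b}"] = {
                "n_genes_scored": len(scores),
                "significant_genes": significant_genes(scores, threshold),
            }

    # proximity of significant SNPs to responsive genes
    responsive = pick_responsive_genes(
        annotation, min(config.n_responsive_proteins, len(annotation)),
        rng=np.random.default_rng(config.seed + 2),
    )
    focal = [g for g in annotation if g.gene_id in set(responsive)]
    summary["proximity"] = {}
    for (a, b), hits in sig_sets.items():
        if len(hits) == 0:
            summary["proximity"][f"{a}-vs-{b}"] = None
            continue
        dist = delta_distance_test(
            hits, focal, annotation,
            n_random=config.n_random,
            seed=int(rng.integers(2**31)),
            label=f"{a}-vs-{b}",
        )
        summary["proximity"][f"{a}-vs-{b}"] = {
            "observed_mean_bp": dist.observed_mean,
            "median_delta_bp": dist.median_delta,
            "ci95": [dist.ci_low, dist.ci_high],
            "excludes_zero": dist.excludes_zero,
            "n_snps": dist.n_snps,
        }

    # proteome contrasts
    prot_params = {"seed": config.seed + 3}
    prot_params.update(config.proteome)
    table, responsive_proteins = simulate_proteome(**prot_params)
    filtered, audit = detection_filter(table, min_reps=config.min_reps)
    omnibus = omnibus_test(filtered)
    contrast_frames = []
    pairs = [("PF", "C"), ("UF", "C"), ("UF", "PF")]
    for x, y in pairs:
        if x in filtered.regimes and y in filtered.regimes:
            contrast_frames.append(pairwise_contrast(filtered, x, y))
    contrasts = pd.concat(contrast_frames, ignore_index=True)
    _write_tsv(contrasts, outdir / "proteome_contrasts.tsv", chash)
    sets = significant_sets(contrasts, alpha=config.alpha)
    summary["proteome"] = {
        "detection_audit": audit,
        "n_omnibus_significant": int((omnibus <= config.alpha).sum()),
        "true_responsive": len(responsive_proteins),
        "contrast_report": sets["report"],
    }

    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary


def _drift_scan(regime_mats, config: RunConfig) -> ScanResult:
    """The drift comparison expressed as a ScanResult (for gene-wise scoring).

    Re-runs the within-regime replicate-pair CMH with the same strata as
    the pooled drift null so gene scores on drift and on between-regime
    scans are directly comparable.
    """
    i, j = config.drift_pair
    mats = list(regime_mats.values())
    maj_a = np.column_stack([m.allele1[:, i - 1] for m in mats])
    min_a = np.column_stack([m.allele2[:, i - 1] for m in mats])
    maj_b = np.column_stack([m.allele1[:, j - 1] for m in mats])
    min_b = np.column_stack([m.allele2[:, j - 1] for m in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = cmh_test_many(
            maj_a, min_a, maj_b, min_b,
            continuity_correction=config.continuity_correction,
        )
    first = mats[0]
    return ScanResult(
        "drift",
        pd.DataFrame(
            {
                "chrom": first.chromosome,
                "pos": first.position,
                "statistic": stat,
                "p": p,
                "neg_log10_p": neg_log10(p),
            }
        ),
    )
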