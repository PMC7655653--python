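"""Synthetic pool-seq experimental-evolution data with known ground truth.

The generator emulates the structure of a thermal evolve-and-resequence
study: one base population of allele frequencies, three thermal regimes
(constant C, predictably fluctuating PF, unpredictably fluctuating UF)
with three replicate populations each, 20 generations of Wright–Fisher
drift (diploid effective size 500, the study's census lower bound) plus
additive genic selection at a configurable minority of loci, and pooled
sequencing as binomial read draws at ~40x coverage.  It also builds a
matching gene annotation, responsive-gene sets, and a regime x replicate
proteome table with a small set of truly responsive proteins.

Everything flows from one seed: identical configurations give
byte-identical fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genewise import GeneModel
from .proteome import ProteinQuantTable
from .syncio import CountMatrix, SiteCounts, write_sync

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_base_frequencies",
    "evolve_replicates",
    "sample_pool_counts",
    "simulate_experiment",
    "simulate_annotation",
    "pick_responsive_genes",
    "simulate_proteome",
]

_CHROM_NAMES = ("2L", "2R", "3L", "3R", "X")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic experiment.

    Defaults mirror the modeled study: 3 regimes x 3 replicates, 20
    generations at Ne = 500, mean pooled coverage 40, and selection (s =
    0.1 per generation, additive) at 5% of sites in the unpredictably
    fluctuating regime only.
    """

    n_sites: int = 10_000
    n_chromosomes: int = 5
    chromosome_length: int = 1_000_000
    effective_size: int = 500
    generations: int = 20
    n_replicates: int = 3
    regimes: tuple[str, ...] = ("C", "PF", "UF")
    coverage: float = 40.0
    fixed_depth: bool = False
    selected_fraction: float = 0.05
    selected_regimes: tuple[str, ...] | None = None  # None -> ("UF",) if present
    selection_coefficient: float = 0.1
    base_freq_distribution: tuple = ("beta", 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.n_chromosomes < 1 or self.n_replicates < 1:
            raise ConfigError("all counts must be positive")
        if self.effective_size < 1:
            raise ConfigError("effective_size must be >= 1")
        if not 0 <= self.selected_fraction <= 1:
            raise ConfigError("selected_fraction must be in [0, 1]")
        if self.coverage < 1:
            raise ConfigError("coverage must be >= 1")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.selected_regimes is None:
            default = ("UF",) if "UF" in self.regimes else ()
            object.__setattr__(self, "selected_regimes", default)
        if unknown := set(self.selected_regimes) - set(self.regimes):
            raise ConfigError(f"selected_regimes not in regimes: {sorted(unknown)}")

    def chromosome_names(self):
        if self.n_chromosomes <= len(_CHROM_NAMES):
            return _CHROM_NAMES[: self.n_chromosomes]
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests.

    ``selected`` and ``s`` have shape (n_sites, n_regimes); neutral sites
    carry s = 0 exactly.  ``final_freqs[regime]`` has shape
    (n_sites, n_replicates).
    """

    regimes: tuple[str, ...]
    base_freq: np.ndarray
    selected: np.ndarray  # bool (n_sites, n_regimes)
    s: np.ndarray  # float (n_sites, n_regimes)
    final_freqs: dict = field(default_factory=dict)

    def selected_sites(self, regime: str) -> np.ndarray:
        return np.flatnonzero(self.selected[:, self.regimes.index(regime)])

    def to_json(self, path) -> None:
        payload = {
            "regimes": list(self.regimes),
            "base_freq": self.base_freq.tolist(),
            "selected": self.selected.astype(int).tolist(),
            "s": self.s.tolist(),
            "final_freqs": {k: v.tolist() for k, v in self.final_freqs.items()},
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)


def simulate_base_frequencies(config: SimConfig, rng=None) -> np.ndarray:
    """Draw base-population allele frequencies, strictly inside (0, 1)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dist = config.base_freq_distribution
    name = dist[0]
    if name == "beta":
        try:
            a, b = float(dist[1]), float(dist[2])
        except (IndexError, ValueError) as exc:
            raise ConfigError(f"beta spectrum needs two shape parameters: {dist}") from exc
        if a <= 0 or b <= 0:
            raise ConfigError("beta shape parameters must be positive")
        freqs = rng.beta(a, b, config.n_sites)
    elif name == "point":
        p = float(dist[1])
        if not 0 < p < 1:
            raise ConfigError("point-mass frequency must be inside (0, 1)")
        freqs = np.full(config.n_sites, p)
    elif name == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        if not 0 <= lo < hi <= 1:
            raise ConfigError("uniform bounds must satisfy 0 <= lo < hi <= 1")
        freqs = rng.uniform(lo, hi, config.n_sites)
    else:
        raise ConfigError(f"unknown base frequency distribution {name!r}")
    # sites are polymorphic by construction; keep floats off the boundary
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def _selection_update(p: np.ndarray, s) -> np.ndarray:
    """One generation of deterministic additive (genic) selection.

    The focal allele has relative fitness 1+s against 1, giving
    p' = p(1+s) / (1 + s p).
    """
    return p * (1.0 + s) / (1.0 + s * p)


def evolve_replicates(base_freqs: np.ndarray, truth: TruthTable, config: SimConfig, rng=None) -> dict:
    """Evolve every (regime, replicate) population independently.

    Per generation: deterministic selection update at selected sites, then
    binomial Wright–Fisher drift over 2*Ne gametes.  Fixation (0 or 1) is
    absorbing.  Results are stored in ``truth.final_freqs`` and returned.
    """
    if np.any((base_freqs <= 0) | (base_freqs >= 1)):
        raise ValueError("base frequencies must be strictly inside (0, 1)")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    two_ne = 2 * config.effective_size
    # independent child streams per (regime, replicate)
    streams = rng.spawn(len(config.regimes) * config.n_replicates)
    for gi, regime in enumerate(config.regimes):
        s_col = truth.s[:, gi]
        has_sel = truth.selected[:, gi]
        final = np.empty((len(base_freqs), config.n_replicates))
        for rep in range(config.n_replicates):
            stream = streams[gi * config.n_replicates + rep]
            p = base_freqs.copy()
            for _ in range(config.generations):
                if has_sel.any():
                    p = np.where(has_sel, _selection_update(p, s_col), p)
                p = stream.binomial(two_ne, p) / two_ne
            final[:, rep] = p
        truth.final_freqs[regime] = final
    return truth.final_freqs


def sample_pool_counts(freqs: np.ndarray, coverage: float, rng, fixed_depth: bool = False) -> np.ndarray:
    """Pooled sequencing of one sample: sync-style (n_sites, 6) counts.

    Depth is Poisson(coverage) per site (or exactly ``coverage`` when
    ``fixed_depth``); reads split binomially between the reference allele
    (slot A) and the alternate allele (slot T) according to the alternate
    frequency ``freqs``.  All other slots stay zero.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    n = len(freqs)
    if fixed_depth:
        depth = np.full(n, int(round(coverage)), dtype=np.int64)
    else:
        depth = rng.poisson(coverage, n)
    alt = rng.binomial(depth, freqs)
    out = np.zeros((n, 6), dtype=np.int64)
    out[:, 0] = depth - alt  # reference -> "A" slot (fixture convention)
    out[:, 1] = alt  # alternate -> "T" slot
    return out


@dataclass
class SimulatedExperiment:
    """Simulated sequencing data plus ground truth and site coordinates."""

    config: SimConfig
    chromosome: np.ndarray  # (n_sites,)
    position: np.ndarray
    truth: TruthTable
    base_counts: np.ndarray  # (n_replicates, n_sites, 6)
    regime_counts: dict  # regime -> (n_replicates, n_sites, 6)

    def sample_labels(self) -> list[str]:
        labels = [f"base_{r + 1}" for r in range(self.config.n_replicates)]
        for regime in self.config.regimes:
            labels += [f"{regime}_{r + 1}" for r in range(self.config.n_replicates)]
        return labels

    def count_matrix(self, group: str) -> CountMatrix:
        """Biallelic counts (reference allele, alternate allele) for a group."""
        arr = self.base_counts if group == "base" else self.regime_counts[group]
        return CountMatrix(
            self.chromosome,
            self.position,
            np.column_stack([arr[r, :, 0] for r in range(arr.shape[0])]),
            np.column_stack([arr[r, :, 1] for r in range(arr.shape[0])]),
        )

    def polymorphic_mask(self, min_minor_count: int = 2) -> np.ndarray:
        """Sites whose pooled minor-allele count across all samples passes."""
        stacks = [self.base_counts] + [self.regime_counts[r] for r in self.config.regimes]
        total = sum(arr.sum(axis=0) for arr in stacks)  # (n_sites, 6)
        ref, alt = total[:, 0], total[:, 1]
        return np.minimum(ref, alt) >= min_minor_count

    def subset(self, mask: np.ndarray) -> "SimulatedExperiment":
        truth = TruthTable(
            self.truth.regimes,
            self.truth.base_freq[mask],
            self.truth.selected[mask],
            self.truth.s[mask],
            {k: v[mask] for k, v in self.truth.final_freqs.items()},
        )
        return SimulatedExperiment(
            self.config,
            self.chromosome[mask],
            self.position[mask],
            truth,
            self.base_counts[:, mask],
            {k: v[:, mask] for k, v in self.regime_counts.items()},
        )

    def to_sync_records(self):
        stacks = [self.base_counts] + [self.regime_counts[r] for r in self.config.regimes]
        for i in range(len(self.position)):
            samples = np.vstack([arr[:, i, :] for arr in stacks])
            yield SiteCounts(str(self.chromosome[i]), int(self.position[i]), "A", samples)

    def write_sync(self, path) -> int:
        return write_sync(self.to_sync_records(), path)


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Run the full genomic simulation: base, evolution, pooled sequencing."""
    rng = np.random.default_rng(config.seed)
    base = simulate_base_frequencies(config, rng)

    chrom_names = config.chromosome_names()
    chromosome = np.asarray(
        [chrom_names[i % len(chrom_names)] for i in range(config.n_sites)], dtype=object
    )
    position = np.empty(config.n_sites, dtype=np.int64)
    for name in chrom_names:
        idx = np.flatnonzero(chromosome == name)
        pos = np.sort(
            rng.choice(config.chromosome_length, size=len(idx), replace=False) + 1
        )
        position[idx] = pos

    n_regimes = len(config.regimes)
    selected = np.zeros((config.n_sites, n_regimes), dtype=bool)
    s = np.zeros((config.n_sites, n_regimes))
    n_selected = int(round(config.selected_fraction * config.n_sites))
    for gi, regime in enumerate(config.regimes):
        if regime in config.selected_regimes and n_selected > 0:
            chosen = rng.choice(config.n_sites, size=n_selected, replace=False)
            selected[chosen, gi] = True
            s[chosen, gi] = config.selection_coefficient
    truth = TruthTable(tuple(config.regimes), base, selected, s)

    evolve_replicates(base, truth, config, rng)

    base_counts = np.stack(
        [
            sample_pool_counts(base, config.coverage, rng, config.fixed_depth)
            for _ in range(config.n_replicates)
        ]
    )
    regime_counts = {}
    for regime in config.regimes:
        final = truth.final_freqs[regime]
        regime_counts[regime] = np.stack(
            [
                sample_pool_counts(final[:, r], config.coverage, rng, config.fixed_depth)
                for r in range(config.n_replicates)
            ]
        )
    return SimulatedExperiment(config, chromosome, position, truth, base_counts, regime_counts)


def simulate_annotation(
    config: SimConfig,
    rng=None,
    n_genes: int = 400,
    min_length: int = 500,
    max_length: int = 5_000,
) -> list[GeneModel]:
    """Random gene intervals across the simulated chromosomes."""
    if max_length >= config.chromosome_length:
        raise ConfigError("chromosome length must exceed gene lengths")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chrom_names = config.chromosome_names()
    genes = []
    for i in range(n_genes):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = int(rng.integers(min_length, max_length + 1))
        start = int(rng.integers(1, config.chromosome_length - length + 1))
        genes.append(GeneModel(f"G{i + 1:05d}", chrom, start, start + length - 1))
    return genes


def pick_responsive_genes(annotation, n: int, rng=None) -> list[str]:
    """Draw n responsive gene ids without replacement (reproducible)."""
    if n > len(annotation):
        raise ValueError(f"requested {n} responsive genes from {len(annotation)}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng
    idx = rng.choice(len(annotation), size=n, replace=False)
    return [annotation[i].gene_id for i in sorted(idx)]


def simulate_proteome(
    n_proteins: int = 1319,
    n_responsive: int = 34,
    effect_size: float = 0.25,
    noise_sd: float = 0.1,
    missing_rate: float = 0.18,
    seed: int | None = 0,
    regimes: tuple[str, ...] = ("C", "PF", "UF"),
    n_replicates: int = 3,
    responsive_regime: str = "UF",
):
    """Regime x replicate protein abundances with planted responsive proteins.

    Log-scale abundance = protein baseline + regime effect + Gaussian
    noise; the regime effect is ``effect_size`` (log units, random sign
    per protein) for responsive proteins in ``responsive_regime`` and zero
    elsewhere.  Detections are dropped independently at ``missing_rate``
    to exercise the detection filter.  Defaults emulate the modeled
    study's scale: 1319 proteins of which 34 respond, most strongly
    distinguishing the unpredictably fluctuating regime.

    Returns ``(ProteinQuantTable, responsive_ids)``.
    """
    if noise_sd < 0 or missing_rate < 0 or missing_rate > 1:
        raise ConfigError("noise_sd must be >= 0 and missing_rate in [0, 1]")
    if n_responsive > n_proteins:
        raise ConfigError("n_responsive cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    responsive = sorted(rng.choice(n_proteins, size=n_responsive, replace=False))
    responsive_ids = [ids[i] for i in responsive]
    sign = rng.choice([-1.0, 1.0], size=n_responsive)

    baseline = rng.normal(10.0, 1.0, n_proteins)
    columns = [(reg, rep + 1) for reg in regimes for rep in range(n_replicates)]
    log_abund = np.empty((n_proteins, len(columns)))
    for j, (reg, _) in enumerate(columns):
        effect = np.zeros(n_proteins)
        if reg == responsive_regime:
            effect[responsive] = sign * effect_size
        log_abund[:, j] = baseline + effect + rng.normal(0.0, noise_sd, n_proteins)
    values = np.exp(log_abund)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan

    table = ProteinQuantTable(
        pd.DataFrame(
            values,
            index=pd.Index(ids, name="protein_id"),
            columns=pd.MultiIndex.from_tuples(columns, names=["regime", "replicate"]),
        )
    )
    return table, responsive_ids
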