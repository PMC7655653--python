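"""Reading, writing and normalizing PoPoolation2-style sync allele counts.

A sync file is tab-separated text with one row per genomic site: chromosome,
1-based position, reference base, then one ``A:T:C:G:N:del`` count string
per pooled sample.  This module parses and validates that format
(gzip-transparently), downsamples counts to a uniform target coverage the
way PoPoolation2's ``downsample-synchronized.pl --method fraction`` does,
and collapses sites to the two most frequent alleles for the 2x2 CMH
machinery.

Coordinate conventions: sync positions are 1-based and kept that way
internally; BED input elsewhere in the package is converted to 1-based
inclusive on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "SiteCounts",
    "BiallelicCounts",
    "CountMatrix",
    "SyncParseError",
    "read_sync",
    "write_sync",
    "downsample_counts",
    "collapse_biallelic",
    "collapse_sync",
]

#: Order of the six count slots in a sync sample column.
NUCLEOTIDES = ("A", "T", "C", "G", "N", "del")
#: Slots eligible to be a retained allele (N and deletions never are).
_ALLELE_SLOTS = (0, 1, 2, 3)


class SyncParseError(ValueError):
    """Malformed sync input; the message names the offending line."""


@dataclass(frozen=True)
class SiteCounts:
    """One sync record: six nucleotide counts per sample at one site."""

    chromosome: str
    position: int  # 1-based
    reference_base: str
    samples: np.ndarray  # shape (n_samples, 6), non-negative ints

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("samples must be an (n_samples, 6) count array")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def depths(self) -> np.ndarray:
        return self.samples.sum(axis=1)


@dataclass(frozen=True)
class BiallelicCounts:
    """A site reduced to its two highest-count alleles, per sample."""

    chromosome: str
    position: int
    alleles: tuple[str, str]  # (major, minor), from {A,T,C,G}
    major: np.ndarray  # (n_samples,)
    minor: np.ndarray


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sync(path) -> Iterator[SiteCounts]:
    """Stream :class:`SiteCounts` records from a (possibly gzipped) sync file."""
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            yield _parse_line(line, lineno)


def _parse_line(line: str, lineno: int) -> SiteCounts:
    fields = line.split("\t")
    if len(fields) < 4:
        raise SyncParseError(
            f"line {lineno}: expected >= 4 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
    except ValueError:
        raise SyncParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
    if pos < 1:
        raise SyncParseError(f"line {lineno}: position {pos} < 1")
    samples = np.empty((len(fields) - 3, 6), dtype=np.int64)
    for j, col in enumerate(fields[3:]):
        parts = col.split(":")
        if len(parts) != 6:
            raise SyncParseError(
                f"line {lineno}: sample column {j + 1} has {len(parts)} fields, "
                f"expected 6 (A:T:C:G:N:del)"
            )
        try:
            samples[j] = [int(x) for x in parts]
        except ValueError:
            raise SyncParseError(
                f"line {lineno}: non-integer count in sample column {j + 1}: {col!r}"
            ) from None
        if (samples[j] < 0).any():
            raise SyncParseError(
                f"line {lineno}: negative count in sample column {j + 1}: {col!r}"
            )
    return SiteCounts(chrom, pos, ref, samples)


def format_sync_record(record: SiteCounts) -> str:
    cols = [record.chromosome, str(record.position), record.reference_base]
    cols.extend(":".join(str(int(c)) for c in row) for row in record.samples)
    return "\t".join(cols)


def write_sync(records: Iterable[SiteCounts], path) -> int:
    """Write sync records; returns the number of lines written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for record in records:
            handle.write(format_sync_record(record) + "\n")
            n += 1
    return n


def _largest_remainder(counts: np.ndarray, target: int) -> np.ndarray:
    """Rescale non-negative integer counts to sum exactly to ``target``.

    Proportions are preserved via largest-remainder (Hamilton) rounding;
    remainder ties break deterministically toward the lower slot index.
    """
    total = counts.sum()
    exact = counts * (target / total)
    floors = np.floor(exact).astype(np.int64)
    short = target - floors.sum()
    if short > 0:
        remainders = exact - floors
        # stable argsort ascending, take the `short` largest remainders;
        # ties resolve to lower slot index because the sort is stable.
        order = np.argsort(-remainders, kind="stable")
        floors[order[:short]] += 1
    return floors


def downsample_counts(record: SiteCounts, target_coverage: int, max_coverage: int = 10_000):
    """Rescale every sample to exactly ``target_coverage`` reads, or drop the site.

    Mirrors the "fraction" method of ``downsample-synchronized.pl``: if any
    sample's depth is below ``target_coverage`` or above ``max_coverage``
    the whole site is dropped (returns ``None``); otherwise each sample's
    six counts are proportionally rescaled to sum exactly to the target.
    """
    if target_coverage < 1:
        raise ValueError("target_coverage must be >= 1")
    depths = record.depths()
    if (depths < target_coverage).any() or (depths > max_coverage).any():
        return None
    new = np.vstack([_largest_remainder(row, target_coverage) for row in record.samples])
    return SiteCounts(record.chromosome, record.position, record.reference_base, new)


def collapse_biallelic(record: SiteCounts, min_minor_count: int = 2):
    """Reduce a site to its two most frequent alleles across all samples.

    The two retained alleles are those with the largest counts summed over
    samples (never N or del; ties break alphabetically, i.e. by slot order
    A, T, C, G re-ranked alphabetically).  Returns ``None`` (monomorphic
    marker) when the pooled minor-allele count is below ``min_minor_count``.
    Reads of non-retained alleles are excluded.
    """
    totals = record.samples.sum(axis=0)[list(_ALLELE_SLOTS)]
    letters = [NUCLEOTIDES[i] for i in _ALLELE_SLOTS]
    # sort by (-count, letter): deterministic alphabetical tie-break
    order = sorted(range(len(letters)), key=lambda i: (-totals[i], letters[i]))
    i_major, i_minor = order[0], order[1]
    if totals[i_minor] < min_minor_count:
        return None
    major = record.samples[:, _ALLELE_SLOTS[i_major]].copy()
    minor = record.samples[:, _ALLELE_SLOTS[i_minor]].copy()
    return BiallelicCounts(
        record.chromosome,
        record.position,
        (letters[i_major], letters[i_minor]),
        major,
        minor,
    )


@dataclass(frozen=True)
class CountMatrix:
    """Biallelic counts for one sample group over many sites.

    ``allele1`` / ``allele2`` are per-site, per-replicate counts of the two
    retained alleles at each site; allele identity is consistent across all
    sample groups sliced from the same sync records (the alleles are ranked
    on the pooled counts of *all* samples before slicing).
    """

    chromosome: np.ndarray  # (n_sites,) str
    position: np.ndarray  # (n_sites,) int, 1-based
    allele1: np.ndarray  # (n_sites, n_replicates)
    allele2: np.ndarray

    def __post_init__(self):
        if self.allele1.shape != self.allele2.shape:
            raise ValueError("allele count arrays must share a shape")
        if len(self.chromosome) != self.allele1.shape[0]:
            raise ValueError("site metadata and count arrays disagree on n_sites")

    @property
    def n_sites(self) -> int:
        return self.allele1.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.allele1.shape[1]

    def subset(self, mask) -> "CountMatrix":
        return CountMatrix(
            self.chromosome[mask], self.position[mask],
            self.allele1[mask], self.allele2[mask],
        )


def collapse_sync(records, groups: dict, min_minor_count: int = 2) -> dict:
    """Collapse sync records to biallelic matrices for named sample groups.

    Alleles are ranked once per site across *all* samples, so every group
    shares the same two alleles at a site.  Sites flagged monomorphic
    (pooled minor count < ``min_minor_count``) are excluded from all groups.

    Parameters
    ----------
    records : iterable of SiteCounts
    groups : mapping of group label -> list of 0-based sample column indices

    Returns
    -------
    dict mapping each group label to a :class:`CountMatrix` (plus key
    ``"__dropped__"`` with the number of monomorphic sites excluded).
    """
    chroms, positions = [], []
    per_group = {label: ([], []) for label in groups}
    dropped = 0
    for record in records:
        collapsed = collapse_biallelic(record, min_minor_count=min_minor_count)
        if collapsed is None:
            dropped += 1
            continue
        chroms.append(record.chromosome)
        positions.append(record.position)
        for label, idx in groups.items():
            a1, a2 = per_group[label]
            a1.append(collapsed.major[idx])
            a2.append(collapsed.minor[idx])
    out = {}
    for label in groups:
        a1, a2 = per_group[label]
        out[label] = CountMatrix(
            np.asarray(chroms, dtype=object),
            np.asarray(positions, dtype=np.int64),
            np.asarray(a1, dtype=np.int64).reshape(len(chroms), -1),
            np.asarray(a2, dtype=np.int64).reshape(len(chroms), -1),
        )
    out["__dropped__"] = dropped
    return out

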