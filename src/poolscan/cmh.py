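"""Cochran–Mantel–Haenszel test for stratified 2x2 allele-count tables.

The CMH test asks whether the allele composition differs consistently
between two conditions (e.g. base vs. evolved population, or two selection
regimes) across K replicate strata.  Each stratum is a 2x2 table with rows
= allele (major / minor) and columns = condition.  The statistic is

    X^2 = ( |sum_k (a_k - E_k)| - c )^2  /  sum_k V_k

with a_k the (major, condition-1) cell, E_k = row1_k * col1_k / n_k,
V_k = row1_k * row2_k * col1_k * col2_k / (n_k^2 (n_k - 1)), and c = 1/2
when the continuity correction is applied (the default, matching the usual
default of R's ``mantelhaen.test`` to which PoPoolation2's cmh-test.pl
delegates) or 0 otherwise.  Strata with a zero row or column margin carry
no information (V_k = 0) and are skipped.  The p-value is the upper tail
of a chi-square distribution with 1 df.

Both a per-site scalar interface (:func:`cmh_test` on a
:class:`StratifiedTable`) and a vectorized interface over many sites
(:func:`cmh_test_many`) are provided; they compute the same statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StratifiedTable",
    "TestResult",
    "build_strata",
    "cmh_test",
    "cmh_test_many",
    "P_FLOOR",
]

#: p-values are floored here before taking -log10, so Manhattan-style
#: output never contains infinities.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class StratifiedTable:
    """K stacked 2x2 tables: rows = allele (major, minor), cols = condition."""

    strata: np.ndarray  # shape (K, 2, 2), non-negative integers
    condition_labels: tuple[str, str] = ("a", "b")

    def __post_init__(self):
        arr = np.asarray(self.strata)
        if arr.ndim != 3 or arr.shape[1:] != (2, 2):
            raise ValueError(f"strata must have shape (K, 2, 2), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("need at least one stratum")
        if (arr < 0).any():
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "strata", arr)

    @property
    def k(self) -> int:
        return self.strata.shape[0]


@dataclass(frozen=True)
class TestResult:
    """Chi-square CMH result with 1 df."""

    statistic: float
    p_value: float
    neg_log10_p: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "neg_log10_p", float(-np.log10(max(self.p_value, P_FLOOR)))
        )


def build_strata(counts_a, counts_b, pairing=None, condition_labels=("a", "b")) -> StratifiedTable:
    """Assemble replicate-paired 2x2 strata from per-replicate (major, minor) counts.

    Parameters
    ----------
    counts_a, counts_b
        Sequences of ``(major_count, minor_count)`` pairs, one per replicate,
        for the two conditions at a single site.
    pairing
        Optional explicit list of 1-based ``(replicate_a, replicate_b)`` index
        pairs.  By default replicate i of condition a is paired with replicate
        i of condition b, which requires equal replicate counts.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    if counts_a.shape[1] != 2 or counts_b.shape[1] != 2:
        raise ValueError("each replicate needs exactly (major, minor) counts")
    if pairing is None:
        if counts_a.shape[0] != counts_b.shape[0]:
            raise ValueError(
                f"replicate counts differ ({counts_a.shape[0]} vs "
                f"{counts_b.shape[0]}); give an explicit pairing"
            )
        pairing = [(i + 1, i + 1) for i in range(counts_a.shape[0])]
    strata = np.empty((len(pairing), 2, 2), dtype=np.int64)
    for k, (ia, ib) in enumerate(pairing):
        maj_a, min_a = counts_a[ia - 1]
        maj_b, min_b = counts_b[ib - 1]
        strata[k] = [[maj_a, maj_b], [min_a, min_b]]
    return StratifiedTable(strata, tuple(condition_labels))


def cmh_test(table: StratifiedTable, continuity_correction: bool = True) -> TestResult:
    """CMH chi-square test (1 df) on a single stratified table."""
    s = table.strata.astype(np.float64)
    stat, p = _cmh_core(
        s[None, :, 0, 0], s[None, :, 1, 0], s[None, :, 0, 1], s[None, :, 1, 1],
        continuity_correction,
    )
    if not np.isfinite(stat[0]):  # pragma: no cover - defensive
        raise AssertionError("non-finite CMH statistic")
    return TestResult(float(stat[0]), float(p[0]))


def cmh_test_many(maj_a, min_a, maj_b, min_b, continuity_correction: bool = True):
    """Vectorized CMH over many sites.

    Parameters
    ----------
    maj_a, min_a, maj_b, min_b
        Arrays of shape ``(n_sites, K)`` holding, per site and replicate
        pair, the major/minor allele counts in conditions a and b.

    Returns
    -------
    (statistic, p_value) : two float arrays of length n_sites.
    """
    maj_a = np.asarray(maj_a, dtype=np.float64)
    min_a = np.asarray(min_a, dtype=np.float64)
    maj_b = np.asarray(maj_b, dtype=np.float64)
    min_b = np.asarray(min_b, dtype=np.float64)
    if not (maj_a.shape == min_a.shape == maj_b.shape == min_b.shape):
        raise ValueError("count arrays must share one (n_sites, K) shape")
    return _cmh_core(maj_a, min_a, maj_b, min_b, continuity_correction)


def _cmh_core(maj_a, min_a, maj_b, min_b, correction):
    row_major = maj_a + maj_b
    row_minor = min_a + min_b
    col_a = maj_a + min_a
    col_b = maj_b + min_b
    n = row_major + row_minor

    # Strata with n <= 1 or a zero margin contribute nothing.
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row_major * col_a / n
        variance = row_major * row_minor * col_a * col_b / (n * n * (n - 1.0))
    informative = (n > 1) & (variance > 0)
    deviation = np.where(informative, maj_a - expected, 0.0)
    variance = np.where(informative, variance, 0.0)

    num = np.abs(deviation.sum(axis=1))
    if correction:
        num = np.maximum(num - 0.5, 0.0)
    var_sum = variance.sum(axis=1)

    degenerate = var_sum <= 0
    if np.isscalar(degenerate):  # pragma: no cover
        degenerate = np.asarray([degenerate])
    if degenerate.any():
        warnings.warn(
            "all strata degenerate for some sites; returning p = 1 there",
            RuntimeWarning,
            stacklevel=3,
        )
    stat = np.where(degenerate, 0.0, num**2 / np.where(degenerate, 1.0, var_sum))
    p = stats.chi2.sf(stat, df=1)
    p = np.where(degenerate, 1.0, p)
    return stat, np.clip(p, P_FLOOR, 1.0)


def neg_log10(p) -> np.ndarray:
    """-log10(p) with the 1e-300 floor applied."""
    return -np.log10(np.clip(np.asarray(p, dtype=np.float64), P_FLOOR, 1.0))
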