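"""Differential-expression pipeline for a regime x replicate protein table.

Input is an iTRAQ-style quantification: one abundance per protein per
(thermal regime, biological replicate) sample, with non-detections as
missing values.  The pipeline is:

1. detection filter — keep proteins detected in at least ``min_reps``
   (default 2 of 3) replicates within *every* regime, avoiding bias from
   non-detected proteins;
2. omnibus one-way ANOVA across regimes on log abundances, per protein;
3. post-hoc pairwise contrasts (two-group tests on log abundances) with
   linear-scale fold changes oriented "X-Y" = mean(X)/mean(Y);
4. significant sets per contrast at p <= alpha (inclusive boundary,
   default 0.05) with pairwise and three-way intersection reporting.

Raw p-values are used by default; a Benjamini–Hochberg adjusted column is
available as an extension via ``adjust="bh"``.

A packaged reference table (``data/regime_contrasts.tsv``: published fold
changes and p-values for 34 thermal-regime-responsive D. simulans
proteins across the PF-C, UF-C and UF-PF contrasts) ships for fixture and
cross-check use; see :func:`load_reference_contrasts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinQuantTable",
    "detection_filter",
    "omnibus_test",
    "pairwise_contrast",
    "significant_sets",
    "load_reference_contrasts",
]

_VAR_EPS = 1e-12


@dataclass
class ProteinQuantTable:
    """Protein x sample abundances; columns are (regime, replicate) pairs.

    Abundances are linear-scale and positive where detected; NaN marks a
    non-detection.
    """

    abundances: pd.DataFrame  # index: protein_id; columns: MultiIndex (regime, replicate)
    descriptions: pd.Series | None = None

    def __post_init__(self):
        cols = self.abundances.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("columns must be a (regime, replicate) MultiIndex")
        reps = {len(cols[cols.get_level_values(0) == r]) for r in self.regimes}
        if len(reps) != 1:
            raise ValueError("every regime must have the same replicate count")
        detected = self.abundances.to_numpy()
        if np.any(detected[np.isfinite(detected)] <= 0):
            raise ValueError("detected abundances must be positive")

    @property
    def regimes(self) -> list[str]:
        return list(dict.fromkeys(self.abundances.columns.get_level_values(0)))

    @property
    def n_proteins(self) -> int:
        return len(self.abundances)

    def detection(self) -> pd.DataFrame:
        return self.abundances.notna()

    @classmethod
    def read_tsv(cls, path) -> "ProteinQuantTable":
        """Read a TSV with columns: protein_id[, description], then one
        ``<regime>_<replicate>`` abundance column per sample."""
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("protein_id")
        desc = None
        if "description" in df.columns:
            desc = df.pop("description")
        tuples = []
        for col in df.columns:
            regime, _, rep = col.rpartition("_")
            tuples.append((regime, int(rep)))
        df.columns = pd.MultiIndex.from_tuples(tuples, names=["regime", "replicate"])
        return cls(df.astype(float), desc)

    def to_tsv(self, path) -> None:
        out = self.abundances.copy()
        out.columns = [f"{r}_{rep}" for r, rep in out.columns]
        if self.descriptions is not None:
            out.insert(0, "description", self.descriptions)
        out.to_csv(path, sep="\t", index_label="protein_id")


def detection_filter(table: ProteinQuantTable, min_reps: int = 2):
    """Keep proteins detected in >= ``min_reps`` replicates within every regime.

    Returns ``(filtered_table, audit)`` where the audit reports input and
    retained counts plus, per regime, how many proteins failed there.
    """
    det = table.detection()
    per_regime = det.T.groupby(level=0).sum().T  # protein x regime detection counts
    ok = (per_regime >= min_reps).all(axis=1)
    audit = {
        "input": int(table.n_proteins),
        "retained": int(ok.sum()),
        "dropped": int((~ok).sum()),
        "failed_per_regime": {
            regime: int((per_regime[regime] < min_reps).sum())
            for regime in table.regimes
        },
        "min_reps": min_reps,
    }
    filtered = ProteinQuantTable(
        table.abundances.loc[ok],
        table.descriptions.loc[ok] if table.descriptions is not None else None,
    )
    return filtered, audit


def _log_groups(table: ProteinQuantTable, regimes=None):
    """Per-protein lists of log-abundance arrays, one per regime, NaN dropped."""
    regimes = regimes or table.regimes
    logged = np.log(table.abundances)
    for protein_id, row in logged.iterrows():
        groups = []
        for regime in regimes:
            vals = row[regime].dropna().to_numpy()
            groups.append(vals)
        yield protein_id, groups


def omnibus_test(table: ProteinQuantTable) -> pd.Series:
    """One-way fixed-effects ANOVA across regimes on log abundances.

    Missing cells are excluded (the standard unbalanced one-way
    decomposition).  Proteins with fewer than two observed regimes, or no
    residual degrees of freedom, get a missing p-value.  A protein with
    zero variance across all observations is a null fit: F = 0, p = 1.
    """
    out = {}
    for protein_id, groups in _log_groups(table):
        groups = [g for g in groups if len(g) > 0]
        n_obs = sum(len(g) for g in groups)
        if len(groups) < 2 or n_obs <= len(groups):
            out[protein_id] = np.nan
            continue
        pooled = np.concatenate(groups)
        if pooled.var() < _VAR_EPS:
            out[protein_id] = 1.0
            continue
        _, p = stats.f_oneway(*groups)
        out[protein_id] = float(p)
    return pd.Series(out, name="p_omnibus")


def pairwise_contrast(table: ProteinQuantTable, regime_x: str, regime_y: str) -> pd.DataFrame:
    """Post-hoc two-group contrast "X-Y": fold change and p-value per protein.

    The test is the equal-variance two-group comparison on log abundances
    (equivalently the two-level one-way ANOVA); the fold change is the
    ratio of linear-scale means, mean(X)/mean(Y), so values above 1 mean
    higher abundance under regime X.
    """
    for regime in (regime_x, regime_y):
        if regime not in table.regimes:
            raise ValueError(f"regime {regime!r} not in table")
    rows = []
    label = f"{regime_x}-{regime_y}"
    lin = table.abundances
    for protein_id, (gx, gy) in _log_groups(table, regimes=[regime_x, regime_y]):
        x_lin = lin.loc[protein_id, regime_x].dropna().to_numpy()
        y_lin = lin.loc[protein_id, regime_y].dropna().to_numpy()
        fc = x_lin.mean() / y_lin.mean() if len(x_lin) and len(y_lin) else np.nan
        if len(gx) < 1 or len(gy) < 1 or len(gx) + len(gy) < 3:
            p = np.nan
        elif np.concatenate([gx, gy]).var() < _VAR_EPS:
            p = 1.0
        else:
            _, p = stats.ttest_ind(gx, gy, equal_var=True)
        rows.append((protein_id, label, fc, float(p) if p == p else np.nan))
    return pd.DataFrame(rows, columns=["protein_id", "contrast", "fold_change", "p_value"])


def significant_sets(contrasts, alpha: float = 0.05, adjust: str | None = None) -> dict:
    """Per-contrast significant protein sets and their intersections.

    ``contrasts`` is a DataFrame with columns protein_id / contrast /
    p_value (e.g. concatenated :func:`pairwise_contrast` outputs), or a
    mapping of label -> such DataFrame.  Significance is p <= alpha
    (boundary inclusive).  ``adjust="bh"`` applies Benjamini–Hochberg
    within each contrast before thresholding (an extension beyond the
    default raw-p workflow).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(contrasts, dict):
        contrasts = pd.concat(contrasts.values(), ignore_index=True)
    sets = {}
    for label, sub in contrasts.groupby("contrast", sort=False):
        p = sub["p_value"].to_numpy(dtype=float)
        ids = sub["protein_id"].to_numpy()
        finite = np.isfinite(p)
        if adjust == "bh":
            p = p.copy()
            p[finite] = stats.false_discovery_control(p[finite], method="bh")
        elif adjust is not None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        sets[label] = set(ids[finite & (p <= alpha)])
    labels = list(sets)
    report = {
        "alpha": alpha,
        "adjust": adjust,
        "sizes": {lab: len(s) for lab, s in sets.items()},
        "pairwise_intersections": {
            f"{a} & {b}": len(sets[a] & sets[b]) for a, b in combinations(labels, 2)
        },
    }
    if len(labels) >= 3:
        triple = set.intersection(*(sets[lab] for lab in labels))
        report["triple_intersection"] = len(triple)
        report["triple_members"] = sorted(triple)
    return {"sets": sets, "report": report}


def load_reference_contrasts() -> pd.DataFrame:
    """Packaged published contrast table (34 proteins; FC and P per contrast).

    Returns a long DataFrame with columns protein_id, description,
    contrast, fold_change, p_value — directly consumable by
    :func:`significant_sets`.
    """
    ref = resources.files("poolscan.data").joinpath("regime_contrasts.tsv")
    with resources.as_file(ref) as path:
        wide = pd.read_csv(path, sep="\t")
    rows = []
    for contrast in ("PF-C", "UF-C", "UF-PF"):
        fc_col, p_col = f"{contrast}_FC", f"{contrast}_P"
        for _, row in wide.iterrows():
            rows.append(
                (row["protein_id"], row["description"], contrast, row[fc_col], row[p_col])
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "description", "contrast", "fold_change", "p_value"]
    )
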