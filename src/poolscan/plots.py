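"""Optional Manhattan-plot export (requires the ``plots`` extra)."""

from __future__ import annotations

import numpy as np


def manhattan(
    scan_result,
    path,
    *,
    thresholds: dict | None = None,
    genes=None,
    title: str | None = None,
):
    """Write a per-chromosome Manhattan plot of -log10(p) to ``path``.

    ``thresholds`` maps label -> p cutoff, drawn as horizontal lines;
    ``genes`` (GeneModel list) adds rug marks at gene positions with line
    width proportional to gene length.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("install the 'plots' extra for Manhattan output") from exc

    data = scan_result.data
    chroms = list(dict.fromkeys(data["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3.2 * len(chroms), 3.2), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = data[data["chrom"] == chrom]
        ax.scatter(sub["pos"], sub["neg_log10_p"], s=3, color="0.4", rasterized=True)
        if thresholds:
            for label, p_cut in thresholds.items():
                ax.axhline(-np.log10(p_cut), lw=0.8, ls="--", label=label)
        if genes:
            for g in genes:
                if g.chromosome == chrom:
                    ax.axvspan(g.start, g.end, color="tab:green", alpha=0.3)
        ax.set_title(chrom)
        ax.set_xlabel("position (bp)")
    axes[0][0].set_ylabel(r"$-\log_{10}(p)$")
    if thresholds:
        axes[0][-1].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
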