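"""Figures: conditional Q-Q panels and the cFDR Manhattan plot."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless; figures are written, never shown

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import QQCurves


def qq_figure(curves_by_trait: Dict[str, QQCurves], path: str) -> None:
    """One conditional Q-Q panel per trait-2 phenotype.

    Each panel overlays the strata curves (all SNPs down to the strictest
    conditioning threshold) against the diagonal; leftward/upward shifts
    at stricter strata indicate shared signal.
    """
    n = len(curves_by_trait)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (trait, curves) in zip(axes[0], curves_by_trait.items()):
        lim = 0.0
        for c in curves.strata:
            if c.n_snps == 0:
                continue
            ax.plot(c.expected, c.observed,
                    label=f"p1 ≤ {c.threshold:g} (s={c.n_snps})", lw=1.2)
            lim = max(lim, c.expected.max(), c.observed.max())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected −log10 p")
        ax.set_ylabel("observed −log10 p")
        ax.set_title(trait)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_figure(plot_table: pd.DataFrame, path: str,
                     alpha: float = 0.05) -> None:
    """Manhattan plot of −log10 cFDR by genomic position, one panel per
    trait, with the discovery threshold line at −log10(alpha)."""
    traits = [t for t in plot_table["trait2"].unique()]
    fig, axes = plt.subplots(len(traits), 1,
                             figsize=(9, 2.2 * len(traits)),
                             squeeze=False, sharex=True)
    chroms = list(dict.fromkeys(plot_table["chrom"]))
    offsets = {}
    off = 0
    for ch in chroms:
        offsets[ch] = off
        off += int(plot_table.loc[plot_table["chrom"] == ch,
                                  "pos"].max()) + 1
    x_all = plot_table["pos"].to_numpy() + np.array(
        [offsets[c] for c in plot_table["chrom"]])
    for ax, trait in zip(axes[:, 0], traits):
        sel = (plot_table["trait2"] == trait).to_numpy()
        colors = np.array([chroms.index(c) % 2
                           for c in plot_table.loc[sel, "chrom"]])
        ax.scatter(x_all[sel], plot_table.loc[sel, "neglog10_cfdr"],
                   c=np.where(colors == 0, "#30508c", "#8ca0c8"), s=4)
        ax.axhline(-np.log10(alpha), color="red", ls="--", lw=0.8)
        ax.set_ylabel("−log10 cFDR")
        ax.set_title(trait, fontsize=9)
    axes[-1, 0].set_xlabel("genomic position (concatenated chromosomes)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
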