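"""Figure export: rarefaction bars, divergence scatter, CGH heat map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_rarefaction(result, fit=None, path=None):
    """Bar plot of mean core-genome size vs genomes sampled, with SD error
    bars and (optionally) the fitted power-law trend line."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(result.xs, result.means, yerr=result.sds, color="0.7", ecolor="0.3")
    if fit is not None:
        xs = np.linspace(result.xs[0], result.xs[-1], 200)
        ax.plot(xs, fit.predict(xs), "k--", lw=1.2,
                label=f"Y = {fit.a:.0f}·X^{fit.b:.4f} {fit.c:+.0f}")
        ax.legend(frameon=False)
    ax.set_xlabel("Number of genomes")
    ax.set_ylabel("Core genome size (genes)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_divergence(pairs, path=None):
    """Two panels: genomic similarity vs MLST identity, and the per-pair
    category fractions of differing genes along the identity gradient."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].scatter(pairs["mlst_identity"], 1.0 - pairs["jaccard_distance"]
                    if "jaccard_distance" in pairs else pairs["genomic_similarity"],
                    s=8, alpha=0.5, color="k")
    axes[0].set_xlabel("MLST identity")
    axes[0].set_ylabel("Genomic similarity (1 − Jaccard)")
    if "frac_hypo_mge" in pairs:
        axes[1].scatter(pairs["mlst_identity"], pairs["frac_hypo_mge"],
                        s=8, alpha=0.5, label="hypothetical/MGE")
        axes[1].scatter(pairs["mlst_identity"], pairs["frac_functional"],
                        s=8, alpha=0.5, label="functional")
        axes[1].set_xlabel("MLST identity")
        axes[1].set_ylabel("Fraction of differing genes")
        axes[1].legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gene_heatmap(signals, assignment, strain_order=None, path=None):
    """Heat map of log2 CGH intensities, genes in dendrogram order and
    strains in a supplied (e.g. clade) order."""
    cols = list(strain_order) if strain_order is not None else list(signals.columns)
    data = np.log2(signals.loc[assignment.gene_order, cols].to_numpy(float) + 1.0)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="log2 signal intensity")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("Strain")
    ax.set_ylabel(f"Auxiliary genes ({assignment.n_groups} groups)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
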