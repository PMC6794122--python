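"""Genomic-island detection along the reference gene order.

A gene is "variable" iff it is auxiliary (outside the soft core). Islands
are maximal runs of consecutive variable genes along the reference
chromosome — consecutive over the array-represented genes only, since loci
absent from the array are invisible to CGH — reported when the run holds at
least ``min_run`` variable genes (default 11, i.e. "more than 10"). Runs
separated by at most ``max_gap`` non-variable genes can be merged.

Completed islands carry GC statistics and the hypothetical / MGE-associated
gene tally whose combined percentage flags likely horizontally acquired
regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, mannwhitneyu

from .errors import ValidationError
from .matrices import CATEGORY_HYPOTHETICAL, CATEGORY_MGE, PresenceAbsenceMatrix
from .divergence import jaccard_condensed


@dataclass
class GenomicIsland:
    """A detected hypervariable run of consecutive variable genes."""

    island_id: int
    start_locus: str
    end_locus: str
    member_genes: list = field(default_factory=list)
    gc_mean: float = np.nan
    gc_sd: float = np.nan
    n_hypothetical: int = 0
    n_mge: int = 0
    hypo_mge_pct: int | None = None

    @property
    def size(self) -> int:
        return len(self.member_genes)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (62.5 -> 63)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def variable_flags(
    pa: PresenceAbsenceMatrix,
    soft_core_genes,
    annotations: pd.DataFrame,
) -> pd.Series:
    """Boolean variable/core flags over the array-represented genes,
    ordered by the reference chromosomal order index."""
    genes = pa.values.index
    order = annotations["order_index"].reindex(genes)
    if order.isna().any():
        missing = list(order.index[order.isna()])[:3]
        raise ValidationError(f"genes lacking an order index, e.g. {missing}")
    ordered = order.sort_values().index
    core = set(soft_core_genes)
    return pd.Series([g not in core for g in ordered], index=ordered, name="variable")


def detect_islands(
    flags: pd.Series,
    min_run: int = 11,
    max_gap: int = 0,
) -> list[GenomicIsland]:
    """Maximal runs of consecutive variable genes, merged across gaps of at
    most ``max_gap`` core genes, reported iff >= ``min_run`` variable genes.

    Island members are the variable genes of the span (so sizes sum to the
    number of auxiliary genes inside detected spans for any ``max_gap``).
    """
    if min_run < 2:
        raise ValidationError("min_run must be >= 2")
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    flat = flags.to_numpy(dtype=bool)
    loci = flags.index.to_numpy()

    # maximal runs of True
    runs: list[tuple[int, int]] = []  # [start, end] inclusive
    i = 0
    n = flat.size
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # merge adjacent runs separated by <= max_gap core genes
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    islands = []
    for start, end in merged:
        members = [loci[k] for k in range(start, end + 1) if flat[k]]
        if len(members) >= min_run:
            islands.append(
                GenomicIsland(
                    island_id=len(islands) + 1,
                    start_locus=members[0],
                    end_locus=members[-1],
                    member_genes=members,
                )
            )
    return islands


def island_stats(island: GenomicIsland, annotations: pd.DataFrame) -> GenomicIsland:
    """Fill in GC mean +/- SD and the hypothetical/MGE tally of an island.

    GC stats use member genes with a GC value (genes lacking one are
    excluded); SD is the sample standard deviation (0 for a single gene).
    The combined hypothetical+MGE percentage is rounded half away from zero.
    """
    ann = annotations.reindex(island.member_genes)
    gc = ann["gc"].dropna().to_numpy(float)
    island.gc_mean = float(gc.mean()) if gc.size else np.nan
    island.gc_sd = float(gc.std(ddof=1)) if gc.size > 1 else 0.0 if gc.size else np.nan
    cats = ann["category"]
    island.n_hypothetical = int((cats == CATEGORY_HYPOTHETICAL).sum())
    island.n_mge = int((cats == CATEGORY_MGE).sum())
    island.hypo_mge_pct = round_half_away(
        100.0 * (island.n_hypothetical + island.n_mge) / island.size
    )
    return island


def island_gc_contrast(
    islands: list[GenomicIsland],
    core_genes,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-island GC deficit relative to the core genome.

    Reports the core GC mean, each island's mean difference from it, and a
    two-sided Mann-Whitney rank test of the island's per-gene GC values
    against the core's. Islands smaller than 3 genes skip the test (p NaN)
    but still report the difference.
    """
    core_gc = annotations.loc[annotations.index.intersection(core_genes), "gc"].dropna()
    if core_gc.empty:
        raise ValidationError("core gene set has no GC values")
    core_mean = float(core_gc.mean())
    rows = []
    for isl in islands:
        gc = annotations["gc"].reindex(isl.member_genes).dropna().to_numpy(float)
        diff = float(gc.mean() - core_mean) if gc.size else np.nan
        if gc.size >= 3:
            p = float(mannwhitneyu(gc, core_gc.to_numpy(), alternative="two-sided").pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "island_id": isl.island_id,
                "island_gc_mean": float(gc.mean()) if gc.size else np.nan,
                "core_gc_mean": core_mean,
                "gc_diff": diff,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def island_congruence(
    island: GenomicIsland,
    pa_auxiliary: PresenceAbsenceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kendall congruence of an island's gene-distribution pattern with the
    overall auxiliary-gene pattern.

    Both patterns are summarized as the vector of pairwise strain Jaccard
    distances — restricted to the island's genes vs over all auxiliary
    genes — and compared by Kendall's tau with a Mantel-style permutation
    p-value (strain labels of the island matrix permuted; one-sided,
    greater). Returns (nan, nan) when either vector has zero variance.
    """
    members = [g for g in island.member_genes if g in set(pa_auxiliary.gene_ids)]
    if len(members) < 2:
        raise ValidationError("island needs >= 2 genes present in the matrix")
    island_B = pa_auxiliary.values.loc[members].to_numpy(bool)
    all_B = pa_auxiliary.values.to_numpy(bool)
    d_island = jaccard_condensed(island_B)
    d_all = jaccard_condensed(all_B)
    if np.nanstd(d_island) == 0 or np.nanstd(d_all) == 0:
        return (np.nan, np.nan)

    tau = kendalltau(d_island, d_all, nan_policy="omit").statistic
    rng = np.random.default_rng(seed)
    n_strains = island_B.shape[1]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_strains)
        d_perm = jaccard_condensed(island_B[:, perm])
        t = kendalltau(d_perm, d_all, nan_policy="omit").statistic
        if not np.isnan(t) and t >= tau:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return (float(tau), float(p))


def islands_table(islands: list[GenomicIsland]) -> pd.DataFrame:
    """Summary table of completed islands (one row per island)."""
    return pd.DataFrame(
        {
            "island_id": [i.island_id for i in islands],
            "start_locus": [i.start_locus for i in islands],
            "end_locus": [i.end_locus for i in islands],
            "gc_mean": [i.gc_mean for i in islands],
            "gc_sd": [i.gc_sd for i in islands],
            "n_hypothetical": [i.n_hypothetical for i in islands],
            "n_mge": [i.n_mge for i in islands],
            "hypo_mge_pct": [i.hypo_mge_pct for i in islands],
            "size": [i.size for i in islands],
        }
    )
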