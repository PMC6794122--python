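"""MLST trees, bootstrap support, NEXUS distance export and gene clustering.

The strain phylogeny is a classic neighbor-joining (NJ) tree built from
pairwise distances (1 - MLST identity by default), with nonparametric
bootstrap support from resampled alignment columns. Distance matrices can
be exported as NEXUS taxa+distances blocks for external split-network
software. Auxiliary genes are grouped by hierarchical clustering of their
log2 signal profiles, the standard way CGH heat maps are organised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .errors import ValidationError
from .divergence import mlst_identity_matrix


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree from a symmetric, zero-diagonal distance matrix.

    Returns an unrooted scikit-bio ``TreeNode`` whose leaf-to-leaf path
    lengths reproduce an additive input matrix exactly. Negative branch
    length estimates (possible on non-additive matrices) are clamped to 0.
    """
    arr = distances.to_numpy(float)
    if arr.shape[0] < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    dm = DistanceMatrix(arr, [str(s) for s in distances.index])
    return _skbio_nj(dm, neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions, each canonicalized as the leaf side not
    containing the lexicographically smallest taxon (order-invariant)."""
    all_leaves = frozenset(l.name for l in tree.tips())
    anchor = min(all_leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(
    seqs: dict[str, str] | pd.Series,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[TreeNode, pd.Series]:
    """NJ tree from identity distances with column-resampling bootstrap.

    Alignment columns are resampled with replacement ``n_boot`` times; each
    replicate yields identity-based distances and an NJ tree, and support
    for an internal edge of the base tree is the percentage of replicates
    containing the same leaf bipartition. Supports are written onto the
    base tree's internal node names (integer percents) and also returned as
    a Series keyed by sorted bipartition. Taxa are canonicalized by sorted
    name before resampling, so supports do not depend on input order.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    items = sorted(dict(seqs).items())
    names = [k for k, _ in items]
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValidationError("sequences must have equal length")
    arr = np.frombuffer("".join(s for _, s in items).encode(), dtype=np.uint8)
    arr = arr.reshape(len(names), -1)
    L = arr.shape[1]

    def identity_distance(a: np.ndarray) -> pd.DataFrame:
        ident = (a[:, None, :] == a[None, :, :]).mean(axis=2)
        d = 1.0 - ident
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=names, columns=names)

    base_tree = nj_tree(identity_distance(arr))
    base_bips = _bipartitions(base_tree)
    counts = {bip: 0 for bip in base_bips}

    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        rep_tree = nj_tree(identity_distance(arr[:, cols]))
        rep_bips = set(_bipartitions(rep_tree))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1

    support = {}
    for bip, node in base_bips.items():
        pct = 100.0 * counts[bip] / n_boot
        node.name = str(int(round(pct)))
        support[",".join(sorted(bip))] = pct
    return base_tree, pd.Series(support, name="support_pct", dtype=float)


def export_nexus_distances(distances: pd.DataFrame, path) -> None:
    """Write a NEXUS file with TAXA and DISTANCES (lower-triangle with
    diagonal) blocks, consumable by split-network software.

    Labels are single-quoted (internal quotes doubled), so any non-empty
    label round-trips; empty labels are rejected.
    """
    labels = [str(s) for s in distances.index]
    if any(lbl == "" for lbl in labels):
        raise ValidationError("taxon labels must be non-empty")
    arr = distances.to_numpy(float)
    n = len(labels)

    def q(lbl: str) -> str:
        return "'" + lbl.replace("'", "''") + "'"

    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};", "  TAXLABELS"]
    lines += [f"    {q(lbl)}" for lbl in labels]
    lines += [
        "  ;",
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"  DIMENSIONS NTAX={n};",
        "  FORMAT TRIANGLE=LOWER DIAGONAL LABELS=LEFT;",
        "  MATRIX",
    ]
    for i, lbl in enumerate(labels):
        row = " ".join(f"{arr[i, j]:.6f}" for j in range(i + 1))
        lines.append(f"    {q(lbl)} {row}")
    lines += ["  ;", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


@dataclass
class GeneGroupAssignment:
    """Hierarchical gene-group assignment of auxiliary genes."""

    groups: pd.Series  # gene -> group id (1..n_groups)
    n_groups: int
    linkage_matrix: np.ndarray
    gene_order: list  # dendrogram leaf order


def cluster_auxiliary_genes(
    signals: pd.DataFrame,
    n_groups: int = 8,
    metric: str = "euclidean",
    method: str = "average",
) -> GeneGroupAssignment:
    """Group auxiliary genes by hierarchical clustering of log2 signals.

    Signals (genes x strains) are log2(x+1)-transformed, genes are
    clustered (Euclidean distance, average linkage by default) and the
    dendrogram is cut into ``n_groups`` flat groups. The returned
    ``gene_order`` is the dendrogram leaf order used for heat-map display.
    """
    if n_groups > signals.shape[0]:
        raise ValidationError("n_groups exceeds the number of genes")
    logged = np.log2(signals.to_numpy(float) + 1.0)
    Z = linkage(logged, method=method, metric=metric)
    flat = fcluster(Z, t=n_groups, criterion="maxclust")
    order = [signals.index[i] for i in leaves_list(Z)]
    return GeneGroupAssignment(
        groups=pd.Series(flat, index=signals.index, name="group"),
        n_groups=int(flat.max()),
        linkage_matrix=Z,
        gene_order=order,
    )


def mlst_distance_matrix(seqs) -> pd.DataFrame:
    """Convenience: 1 - identity distances from concatenated MLST sequences."""
    ident = mlst_identity_matrix(seqs)
    return 1.0 - ident
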