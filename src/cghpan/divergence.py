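"""Gene-content divergence versus phylogenetic relatedness.

Gene-content dissimilarity between strains is the Jaccard distance over
present-gene sets; phylogenetic relatedness is the pairwise identity of
concatenated MLST housekeeping-gene sequences. The module associates the
two (Spearman rank correlation with a Mantel permutation p-value),
decomposes each pair's differing genes into hypothetical/MGE-associated
versus functional contributions across the identity gradient, and tallies
differences per COG functional category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon

from .errors import ValidationError
from .matrices import (
    CATEGORY_HYPOTHETICAL,
    CATEGORY_MGE,
    PresenceAbsenceMatrix,
)

#: identity-bin edges: pooled <0.95 bin, then width 0.004 up to 1.0
DEFAULT_BIN_EDGES = tuple([0.0] + list(np.round(np.arange(0.95, 1.0, 0.004), 3)) + [1.0])
#: lower edge of the high-identity bin used for the dominance contrast
HIGH_IDENTITY_LOWER = 0.982


def jaccard_condensed(B: np.ndarray) -> np.ndarray:
    """Condensed (upper-triangle) Jaccard distances between strain columns
    of a genes x strains boolean matrix. Pairs with an empty union are NaN."""
    Bi = B.astype(np.int64)
    inter = Bi.T @ Bi
    sizes = Bi.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    iu = np.triu_indices(B.shape[1], k=1)
    return d[iu]


def jaccard_matrix(pa: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Strains x strains Jaccard distance matrix: d = 1 - |A&B| / |A|B|."""
    B = pa.values.to_numpy(bool)
    sizes = B.sum(axis=0)
    if (sizes == 0).any():
        empty = [s for s, n in zip(pa.strain_ids, sizes) if n == 0]
        raise ValidationError(f"strains with empty gene sets: {empty}")
    Bi = B.astype(np.int64)
    inter = Bi.T @ Bi
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pa.strain_ids, columns=pa.strain_ids)


def mlst_identity_matrix(seqs: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Pairwise identity (matching positions / length) of equal-length
    ungapped concatenated MLST sequences."""
    items = list(seqs.items())
    if not items:
        raise ValidationError("no sequences given")
    names = [k for k, _ in items]
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(s for _, s in items).encode(), dtype=np.uint8)
    arr = arr.reshape(len(items), -1)
    ident = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    np.fill_diagonal(ident, 1.0)
    return pd.DataFrame(ident, index=names, columns=names)


def _condensed(matrix: pd.DataFrame, strains: list[str]) -> np.ndarray:
    m = matrix.loc[strains, strains].to_numpy(float)
    iu = np.triu_indices(len(strains), k=1)
    return m[iu]


def pair_index(strains: list[str]) -> pd.MultiIndex:
    iu = np.triu_indices(len(strains), k=1)
    return pd.MultiIndex.from_arrays(
        [np.asarray(strains)[iu[0]], np.asarray(strains)[iu[1]]],
        names=["strain_a", "strain_b"],
    )


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int


def content_vs_phylogeny(
    jaccard: pd.DataFrame,
    identity: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, MantelResult]:
    """Spearman association between genomic similarity (1 - Jaccard
    distance) and MLST identity over unordered strain pairs.

    The p-value is a Mantel permutation test (strain labels of the identity
    matrix permuted, one-sided greater), respecting the non-independence of
    pairs sharing a strain. With constant similarity or identity across
    pairs the correlation is undefined and returned as NaN.
    """
    strains = [s for s in jaccard.index if s in set(identity.index)]
    if len(strains) < 3:
        raise ValidationError("correlation needs at least 3 shared strains")
    sim = 1.0 - _condensed(jaccard, strains)
    ident = _condensed(identity, strains)
    pairs = pd.DataFrame(
        {"jaccard_distance": 1.0 - sim, "genomic_similarity": sim, "mlst_identity": ident},
        index=pair_index(strains),
    )
    if np.std(sim) == 0 or np.std(ident) == 0:
        return pairs, MantelResult(np.nan, np.nan, n_permutations)

    rho = spearmanr(sim, ident).statistic
    rng = np.random.default_rng(seed)
    I = identity.loc[strains, strains].to_numpy(float)
    iu = np.triu_indices(len(strains), k=1)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(strains))
        r = spearmanr(sim, I[np.ix_(perm, perm)][iu]).statistic
        if not np.isnan(r) and r >= rho:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return pairs, MantelResult(float(rho), float(p), n_permutations)


def _category_masks(annotations: pd.DataFrame, genes: pd.Index):
    cats = annotations["category"].reindex(genes)
    if cats.isna().any():
        missing = list(cats.index[cats.isna()])[:3]
        raise ValidationError(f"genes lacking a category, e.g. {missing}")
    hypo_mge = ((cats == CATEGORY_HYPOTHETICAL) | (cats == CATEGORY_MGE)).to_numpy()
    return hypo_mge, ~hypo_mge


def _pairwise_diff_counts(B: np.ndarray) -> np.ndarray:
    """Condensed symmetric-difference sizes between strain columns."""
    Bi = B.astype(np.int64)
    inter = Bi.T @ Bi
    sizes = Bi.sum(axis=0)
    diff = sizes[:, None] + sizes[None, :] - 2 * inter
    iu = np.triu_indices(B.shape[1], k=1)
    return diff[iu]


def decompose_divergence(
    pa: PresenceAbsenceMatrix,
    annotations: pd.DataFrame,
    identity: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split each strain pair's differing genes into hypothetical/MGE vs
    functional contributions, summarized per MLST-identity bin.

    Per pair, differing genes are the symmetric difference of presence
    sets; fractions are of that pair's total differing genes. Per identity
    bin, a paired two-sided Wilcoxon signed-rank test contrasts the two
    fractions across pairs (skipped and flagged for bins with <2 usable
    pairs or all-zero contrasts).
    """
    strains = [s for s in pa.strain_ids if s in set(identity.index)]
    B = pa.values[strains].to_numpy(bool)
    hypo_mge, functional = _category_masks(annotations, pa.values.index)

    n_total = _pairwise_diff_counts(B)
    n_hm = _pairwise_diff_counts(B[hypo_mge])
    n_fn = _pairwise_diff_counts(B[functional])
    ident = _condensed(identity, strains)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_hm = np.where(n_total > 0, n_hm / np.maximum(n_total, 1), np.nan)
        frac_fn = np.where(n_total > 0, n_fn / np.maximum(n_total, 1), np.nan)
    pairs = pd.DataFrame(
        {
            "mlst_identity": ident,
            "n_diff_total": n_total,
            "n_diff_hypo_mge": n_hm,
            "n_diff_functional": n_fn,
            "frac_hypo_mge": frac_hm,
            "frac_functional": frac_fn,
        },
        index=pair_index(strains),
    )

    edges = np.asarray(bin_edges, float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # right-closed top bin so identity 1.0 lands in [.., 1.0]
        in_bin = (ident >= lo) & ((ident < hi) | (hi == edges[-1]) & (ident <= hi))
        sub = pairs[in_bin].dropna(subset=["frac_hypo_mge"])
        row = {
            "identity_low": lo,
            "identity_high": hi,
            "n_pairs": int(in_bin.sum()),
            "mean_frac_hypo_mge": float(sub["frac_hypo_mge"].mean()) if len(sub) else np.nan,
            "mean_frac_functional": float(sub["frac_functional"].mean()) if len(sub) else np.nan,
            "p_value": np.nan,
            "test_skipped": True,
        }
        if len(sub) >= 2:
            x = sub["frac_hypo_mge"].to_numpy()
            y = sub["frac_functional"].to_numpy()
            if np.any(x != y):
                row["p_value"] = float(wilcoxon(x, y, alternative="two-sided").pvalue)
                row["test_skipped"] = False
        rows.append(row)
    return pairs, pd.DataFrame(rows)


def cog_divergence(
    pa: PresenceAbsenceMatrix,
    annotations: pd.DataFrame,
    identity: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-COG-letter differing-gene counts across the identity gradient.

    Returns (per-pair long table, per-bin summary). The summary ranks COG
    letters by their mean differing-gene count per pair within each bin;
    letters with the greatest counts diverge fastest.
    """
    cog = annotations["cog"].reindex(pa.values.index)
    letters = sorted(set(cog.dropna()))
    if not letters:
        raise ValidationError("no COG letters in the annotation table")
    strains = [s for s in pa.strain_ids if s in set(identity.index)]
    B = pa.values[strains].to_numpy(bool)
    ident = _condensed(identity, strains)
    idx = pair_index(strains)

    per_letter = {
        letter: _pairwise_diff_counts(B[(cog == letter).to_numpy()]) for letter in letters
    }
    pairs = pd.DataFrame(per_letter, index=idx)
    pairs.insert(0, "mlst_identity", ident)

    edges = np.asarray(bin_edges, float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (ident >= lo) & ((ident < hi) | (hi == edges[-1]) & (ident <= hi))
        if not in_bin.any():
            continue
        for letter in letters:
            rows.append(
                {
                    "identity_low": lo,
                    "identity_high": hi,
                    "cog": letter,
                    "n_pairs": int(in_bin.sum()),
                    "mean_n_diff": float(pairs.loc[in_bin, letter].mean()),
                }
            )
    summary = pd.DataFrame(rows)
    if len(summary):
        summary["rank_in_bin"] = summary.groupby(["identity_low", "identity_high"])[
            "mean_n_diff"
        ].rank(ascending=False, method="min")
    return pairs, summary
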