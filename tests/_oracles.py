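"""Independent brute-force oracles used to check the implementations.

Everything here is deliberately naive — exhaustive loops, string splitting,
closed forms — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import re

import numpy as np


def brute_force_min_fdr(signals: np.ndarray, truth: np.ndarray):
    """Exhaustive min-FDR search over all distinct observed values.

    Returns (cutoff, fdr) with ties broken toward the smallest cutoff.
    A cutoff with no presence call is skipped (undefined FDR).
    """
    sig = signals.ravel()
    tru = truth.ravel().astype(bool)
    best = None
    for c in sorted(set(sig.tolist())):
        calls = sig >= c
        tp = int((calls & tru).sum())
        fp = int((calls & ~tru).sum())
        if tp + fp == 0:
            continue
        fdr = fp / (fp + tp)
        if best is None or fdr < best[1] - 1e-15:
            best = (c, fdr)
    return best


def islands_by_splitting(flags, min_run: int, max_gap: int):
    """Island spans via string splitting: regions are maximal substrings of
    the 0/1 flag string not containing a run of more than ``max_gap``
    zeros, trimmed to their variable ends; kept iff they hold at least
    ``min_run`` ones. Returns lists of variable-gene positions."""
    s = "".join("1" if f else "0" for f in flags)
    islands = []
    pos = 0
    parts = re.split("(" + "0" * (max_gap + 1) + "+)", s)
    for k, part in enumerate(parts):
        if k % 2 == 0:  # odd entries are the captured zero-run separators
            ones = [pos + i for i, ch in enumerate(part) if ch == "1"]
            if len(ones) >= min_run:
                islands.append(ones)
        pos += len(part)
    return islands


def kendall_tau_b(x, y) -> float:
    """Tau-b by O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom


def manual_ranks(x) -> np.ndarray:
    """Average ranks computed by explicit sorting, no scipy."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_manual(x, y) -> float:
    """Spearman rho as Pearson correlation of manually computed ranks."""
    return float(np.corrcoef(manual_ranks(x), manual_ranks(y))[0, 1])


def rarefaction_exact_means(B: np.ndarray, prefix_cols=()) -> np.ndarray:
    """Exact expected strict-intersection core sizes: average over every
    ordering of the non-prefix columns (small n only)."""
    n = B.shape[1]
    rest = [c for c in range(n) if c not in set(prefix_cols)]
    totals = np.zeros(n)
    count = 0
    for perm in itertools.permutations(rest):
        order = list(prefix_cols) + list(perm)
        inter = np.ones(B.shape[0], dtype=bool)
        for x, col in enumerate(order):
            inter &= B[:, col]
            totals[x] += inter.sum()
        count += 1
    return totals / count


def naive_jaccard(B: np.ndarray) -> np.ndarray:
    """Full Jaccard distance matrix by a double loop over strain columns."""
    n = B.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = B[:, i].astype(bool), B[:, j].astype(bool)
            union = (a | b).sum()
            D[i, j] = 1 - (a & b).sum() / union if union else np.nan
    return D


def naive_symdiff(B: np.ndarray) -> np.ndarray:
    """Symmetric-difference gene counts by a double loop."""
    n = B.shape[1]
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            D[i, j] = int((B[:, i].astype(bool) ^ B[:, j].astype(bool)).sum())
    return D
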