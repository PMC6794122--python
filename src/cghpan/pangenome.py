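"""Core/pan-genome partitioning, rarefaction and the power-law hard core.

The "soft" core is the set of genes present in more than a prevalence
threshold (default >90%) of strains; its complement is the auxiliary
genome. The core-genome rarefaction curve tracks the mean size of the
strict intersection of gene sets as genomes are added in random order, and
a three-parameter power law Y = a*X**b + c fitted to the curve yields the
asymptotic "hard" core estimate, reported as |c|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import FittingError, ValidationError
from .matrices import PresenceAbsenceMatrix


class SoftCorePartition(NamedTuple):
    core: pd.Index
    auxiliary: pd.Index


@dataclass
class RarefactionResult:
    """Mean/SD strict-intersection core size per number of sampled genomes."""

    xs: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_reps: int
    fixed_prefix: tuple
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_genomes": self.xs, "mean": self.means, "sd": self.sds})


@dataclass
class PowerLawFit:
    """Fitted Y = a*X**b + c with hard core reported as |c|."""

    a: float
    b: float
    c: float
    hard_core: float
    rss: float

    def predict(self, xs) -> np.ndarray:
        return self.a * np.asarray(xs, float) ** self.b + self.c


def gene_prevalence(pa: PresenceAbsenceMatrix) -> pd.Series:
    """Fraction of strains carrying each gene."""
    if pa.n_strains < 1:
        raise ValidationError("prevalence requires at least one strain")
    return pa.values.mean(axis=1).rename("prevalence")


def soft_core(pa: PresenceAbsenceMatrix, threshold: float = 0.90) -> SoftCorePartition:
    """Partition genes into the soft core (prevalence strictly > threshold)
    and the auxiliary set (everything else)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly between 0 and 1")
    prev = gene_prevalence(pa)
    mask = prev > threshold
    return SoftCorePartition(prev.index[mask], prev.index[~mask])


def core_rarefaction(
    pa: PresenceAbsenceMatrix,
    n_reps: int = 100,
    seed: int | None = None,
    fixed_prefix: Sequence[str] = (),
) -> RarefactionResult:
    """Strict-intersection core size as genomes accumulate.

    For each replicate, genomes are ordered as ``fixed_prefix`` (in the
    given order) followed by the remaining strains sampled uniformly
    without replacement; the core at x genomes is the number of genes
    present in all of the first x. SD is 0 for x <= len(fixed_prefix).
    """
    strains = pa.strain_ids
    prefix = list(fixed_prefix)
    if len(prefix) > len(strains):
        raise ValidationError("fixed_prefix is longer than the strain set")
    missing = set(prefix) - set(strains)
    if missing:
        raise ValidationError(f"fixed_prefix strains not in matrix: {sorted(missing)}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")

    col_of = {s: i for i, s in enumerate(strains)}
    prefix_idx = np.array([col_of[s] for s in prefix], dtype=int)
    rest_idx = np.array([i for s, i in col_of.items() if s not in set(prefix)], dtype=int)

    values = pa.values.to_numpy()
    rng = np.random.default_rng(seed)
    sizes = np.empty((n_reps, len(strains)), dtype=np.int64)
    for r in range(n_reps):
        order = np.concatenate([prefix_idx, rng.permutation(rest_idx)])
        cum = np.logical_and.accumulate(values[:, order], axis=1)
        sizes[r] = cum.sum(axis=0)

    return RarefactionResult(
        xs=np.arange(1, len(strains) + 1),
        means=sizes.mean(axis=0),
        sds=sizes.std(axis=0, ddof=0),
        n_reps=n_reps,
        fixed_prefix=tuple(prefix),
        seed=seed,
    )


_B_STARTS = (-1.0, -0.5, -0.2, -0.08, 0.08, 0.2, 0.5)


def fit_power_law(result: RarefactionResult) -> PowerLawFit:
    """Unconstrained nonlinear least squares of the rarefaction means on
    Y = a*X**b + c, multi-start over the exponent.

    The hard-core estimate is |c|: on a decaying curve the fit converges to
    b < 0 with c > 0 the asymptote, but the sign of c is preserved in the
    output so degenerate parameterizations remain visible.
    """
    xs = np.asarray(result.xs, float)
    ys = np.asarray(result.means, float)
    if np.unique(xs).size < 4:
        raise ValidationError("power-law fit needs at least 4 distinct x values")

    def model(x, a, b, c):
        return a * np.power(x, b) + c

    best = None
    best_rss = np.inf
    scale = max(ys.max() - ys.min(), 1.0)
    for b0 in _B_STARTS:
        for a0, c0 in ((scale, ys.min()), (ys[0], 0.0), (-scale, ys.max())):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, _ = curve_fit(model, xs, ys, p0=(a0, b0, c0), maxfev=20000)
            except (RuntimeError, TypeError):
                continue
            rss = float(np.sum((model(xs, *popt) - ys) ** 2))
            if np.isfinite(rss) and rss < best_rss:
                best, best_rss = popt, rss
    if best is None:
        raise FittingError("power-law fit did not converge from any start")
    a, b, c = (float(v) for v in best)
    return PowerLawFit(a=a, b=b, c=c, hard_core=abs(c), rss=best_rss)


def category_counts(
    core_genes: pd.Index,
    auxiliary_genes: pd.Index,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-COG-letter gene counts and fractions for core vs auxiliary.

    Genes without a COG letter are excluded, matching the usual convention
    for COG distribution summaries.
    """
    cog = annotations["cog"].dropna()
    rows = []
    for partition, genes in (("core", core_genes), ("auxiliary", auxiliary_genes)):
        letters = cog.reindex(genes).dropna()
        counts = letters.value_counts().sort_index()
        total = int(counts.sum())
        for letter, n in counts.items():
            rows.append(
                {
                    "partition": partition,
                    "cog": letter,
                    "count": int(n),
                    "fraction": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["partition", "cog", "count", "fraction"])
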