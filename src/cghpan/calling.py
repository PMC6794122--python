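"""Presence/absence calling from one-channel CGH probe intensities.

The pipeline mirrors standard closed-format array processing: per-array
background subtraction using negative-control probes, per-gene median
summarization over that gene's probes, a single global intensity cutoff
optimized to minimize the false-discovery rate (FDR) against strains with
sequenced genomes, and per-strain FDR validation.

A "discovery" is a presence call, so FDR = FP / (FP + TP) where a false
positive is a present call for a gene the sequenced genome lacks. The
false-negative rate (missed present genes) is reported alongside for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import GeneSignalMatrix, PresenceAbsenceMatrix, ProbeSignalMatrix


@dataclass
class CutoffResult:
    """Outcome of the FDR-minimizing cutoff search.

    ``fdr``/``fnr`` are pooled over the reference strains; ``per_strain_fdr``
    gives the per-strain breakdown; ``grid`` is every cutoff evaluated.
    """

    cutoff: float
    fdr: float
    fnr: float
    per_strain_fdr: pd.Series
    grid: np.ndarray
    fdr_grid: np.ndarray

    def as_dict(self) -> dict:
        return {
            "cutoff": float(self.cutoff),
            "fdr": float(self.fdr),
            "fnr": float(self.fnr),
            "per_strain_fdr": {k: float(v) for k, v in self.per_strain_fdr.items()},
        }


def normalize_signals(raw: ProbeSignalMatrix) -> ProbeSignalMatrix:
    """Subtract each array's mean negative-control intensity; floor at zero.

    Background correction is per strain column: the mean signal over that
    array's control probes is subtracted from every spot. Intensities are
    physically non-negative, so values driven below zero are clipped to 0.
    Control probes are retained (normalized like any other spot) for audit.
    """
    controls = [p for p in raw.values.index if p in raw.control_probes]
    if not controls:
        raise ValidationError("cannot normalize without negative-control probes")
    background = raw.values.loc[controls].mean(axis=0)
    normalized = (raw.values - background).clip(lower=0.0)
    return ProbeSignalMatrix(normalized, raw.probe_to_gene, raw.control_probes)


def summarize_gene_signals(normalized: ProbeSignalMatrix) -> GeneSignalMatrix:
    """Per gene and strain, the median of the gene's normalized probe values.

    Control probes (which map to no gene) are dropped. The median is the
    numpy convention: midpoint of the two central values for even counts.
    """
    mapped = normalized.probe_to_gene.index.intersection(normalized.values.index)
    gene_of = normalized.probe_to_gene.loc[mapped]
    gene_values = normalized.values.loc[mapped].groupby(gene_of.to_numpy()).median()
    gene_values.index.name = "locus_tag"
    return GeneSignalMatrix(gene_values)


def _pooled_rates(signals: np.ndarray, truth: np.ndarray, grid: np.ndarray):
    """Vectorized FP/(FP+TP) and FN/(FN+TP) over a cutoff grid.

    For cutoff c a presence call is signal >= c, so FP(c) counts truth-absent
    signals >= c and TP(c) truth-present signals >= c; both are suffix counts
    of the sorted signal arrays.
    """
    present = np.sort(signals[truth])
    absent = np.sort(signals[~truth])
    tp = present.size - np.searchsorted(present, grid, side="left")
    fp = absent.size - np.searchsorted(absent, grid, side="left")
    fn = present.size - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(tp + fp > 0, fp / np.maximum(tp + fp, 1), np.nan)
        fnr = np.where(present.size > 0, fn / max(present.size, 1), np.nan)
    return fdr, fnr


def optimize_cutoff(
    signals: GeneSignalMatrix,
    truth: PresenceAbsenceMatrix,
    extra_grid=None,
) -> CutoffResult:
    """Find the presence cutoff minimizing pooled FDR on reference strains.

    ``truth`` holds the sequenced (reference) strains' true gene content;
    only strains shared between ``signals`` and ``truth`` enter the search.
    The default grid is every distinct observed gene-signal value on those
    strains (the exact optimum lies on it, since FDR only changes there);
    ``extra_grid`` appends fixed cutoffs. Ties in FDR break toward the
    smallest cutoff. Cutoffs at which no presence call is made (undefined
    FDR) are excluded from the minimization.
    """
    shared = [s for s in truth.strain_ids if s in set(signals.strain_ids)]
    if not shared:
        raise ValidationError("truth shares no strains with the signal matrix")
    genes = signals.values.index.intersection(truth.values.index)
    sig = signals.values.loc[genes, shared].to_numpy().ravel()
    tru = truth.values.loc[genes, shared].to_numpy().ravel()
    if not tru.any():
        raise ValidationError("truth has zero present genes; FDR is undefined")

    grid = np.unique(sig)
    if extra_grid is not None:
        grid = np.unique(np.concatenate([grid, np.asarray(extra_grid, float)]))
    fdr_grid, fnr_grid = _pooled_rates(sig, tru, grid)

    finite = np.where(~np.isnan(fdr_grid))[0]
    if finite.size == 0:
        raise ValidationError("no cutoff yields any presence call")
    # argmin returns the first (= smallest cutoff) among ties: grid is sorted
    best = finite[np.argmin(fdr_grid[finite])]
    cutoff = float(grid[best])

    calls = call_presence(signals, cutoff)
    per_strain = validate_fdr(calls, truth)
    return CutoffResult(
        cutoff=cutoff,
        fdr=float(fdr_grid[best]),
        fnr=float(fnr_grid[best]),
        per_strain_fdr=per_strain,
        grid=grid,
        fdr_grid=fdr_grid,
    )


def call_presence(signals: GeneSignalMatrix, cutoff: float) -> PresenceAbsenceMatrix:
    """Call a gene present in a strain iff its signal >= cutoff.

    The boundary counts as present: ">= cutoff" is the conventional reading
    of a detection threshold.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be non-negative")
    return PresenceAbsenceMatrix(signals.values >= cutoff, cutoff_used=float(cutoff))


def validate_fdr(calls: PresenceAbsenceMatrix, truth: PresenceAbsenceMatrix) -> pd.Series:
    """Per-strain FDR of presence calls against sequenced-genome truth.

    Strains in ``truth`` must be a subset of the called strains. A strain
    with zero presence calls has undefined FDR and is reported as NaN.
    """
    missing = set(truth.strain_ids) - set(calls.strain_ids)
    if missing:
        raise ValidationError(f"truth strains absent from calls: {sorted(missing)}")
    genes = calls.values.index.intersection(truth.values.index)
    out = {}
    for strain in truth.strain_ids:
        called = calls.values.loc[genes, strain].to_numpy()
        actual = truth.values.loc[genes, strain].to_numpy()
        n_calls = int(called.sum())
        fp = int((called & ~actual).sum())
        out[strain] = fp / n_calls if n_calls else np.nan
    return pd.Series(out, name="fdr")
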