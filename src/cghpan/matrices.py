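"""Core in-memory containers for the CGH pipeline.

All matrices are thin dataclass wrappers around pandas DataFrames so that
probe, gene and strain identifiers travel with the numbers. The central
object is :class:`PresenceAbsenceMatrix` (genes x strains booleans), which
every downstream stage (pan-genome, islands, divergence, trees) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Annotation category labels.
CATEGORY_FUNCTIONAL = "functional"
CATEGORY_HYPOTHETICAL = "hypothetical"
CATEGORY_MGE = "MGE"
CATEGORIES = (CATEGORY_FUNCTIONAL, CATEGORY_HYPOTHETICAL, CATEGORY_MGE)

#: Required columns of a gene annotation table (indexed by locus tag).
ANNOTATION_COLUMNS = ("order_index", "gc", "category", "cog")


@dataclass
class ProbeSignalMatrix:
    """Probe-level hybridization intensities across strains.

    Parameters
    ----------
    values
        probes x strains intensities; index = probe ids, columns = strain ids.
    probe_to_gene
        Mapping from non-control probe id to its target locus tag.
    control_probes
        Ids of negative-control probes (present in ``values``, absent from
        ``probe_to_gene``).
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    control_probes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.control_probes = frozenset(self.control_probes)
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("probe signal values must be finite")
        if self.values.columns.has_duplicates:
            raise ValidationError("strain ids must be unique")
        if self.values.index.has_duplicates:
            raise ValidationError("probe ids must be unique")
        probe_ids = set(self.values.index)
        mapped = set(self.probe_to_gene.index)
        non_control = probe_ids - self.control_probes
        if non_control - mapped:
            missing = sorted(non_control - mapped)[:3]
            raise ValidationError(
                f"non-control probes without a gene mapping, e.g. {missing}"
            )
        if mapped & self.control_probes:
            raise ValidationError("control probes must not map to genes")

    @property
    def strain_ids(self) -> list:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)


@dataclass
class GeneSignalMatrix:
    """Gene-level normalized intensities (median over a gene's probes)."""

    values: pd.DataFrame  # genes x strains

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("gene signals must be non-negative")
        if self.values.index.has_duplicates:
            raise ValidationError("gene ids must be unique")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def strain_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class PresenceAbsenceMatrix:
    """Genes x strains boolean presence calls."""

    values: pd.DataFrame
    cutoff_used: float | None = None

    def __post_init__(self):
        self.values = self.values.astype(bool)

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def strain_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_strains(self) -> int:
        return self.values.shape[1]

    def restrict_strains(self, strains) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.values[list(strains)], self.cutoff_used)

    def restrict_genes(self, genes) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.values.loc[list(genes)], self.cutoff_used)


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table (index = locus tag).

    Required columns: ``order_index`` (position along the reference
    chromosome), ``gc`` (fraction), ``category`` (functional | hypothetical |
    MGE) and ``cog`` (single COG letter or missing).
    """
    for col in ("order_index", "gc", "category"):
        if col not in annotations.columns:
            raise ValidationError(f"annotation table lacks column {col!r}")
    bad = set(annotations["category"].dropna()) - set(CATEGORIES)
    if bad:
        raise ValidationError(f"unknown annotation categories: {sorted(bad)}")
    if annotations.index.has_duplicates:
        raise ValidationError("locus tags must be unique")
    return annotations
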