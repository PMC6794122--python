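"""Synthetic strain collections with known ground truth.

The generator emulates the design of an intraspecific bacterial CGH study:
a clade-structured strain collection probed on a closed-format array built
from reference genomes. Ground-truth gene content is assembled from

* a universal core (present in every strain),
* contiguous genomic-island blocks assigned to single clades, with a
  configurable depressed-GC offset,
* scattered background auxiliary genes with clade-level presence patterns
  (present in a random subset of clades), and
* per-strain Bernoulli gain/loss "turnover" restricted to the designated
  hypothetical/MGE background pool, so that intra-clade gene-content
  differences are hypothetical/MGE-dominated by construction while
  inter-clade differences are dominated by functional clade blocks.

Probe intensities are log-normal ("present" vs "absent"/background
distributions; a one-channel array produces positive, right-skewed
signals), negative-control probes draw from background, and concatenated
MLST sequences evolve along a two-level clade tree by Jukes-Cantor-style
per-site substitution. All randomness flows from one integer seed.
"""

from __future__ import annotations

import io as _io
import string
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .errors import ConfigError
from .islands import GenomicIsland, island_stats
from .matrices import (
    CATEGORY_FUNCTIONAL,
    CATEGORY_HYPOTHETICAL,
    CATEGORY_MGE,
    PresenceAbsenceMatrix,
    ProbeSignalMatrix,
)

#: COG letters used for functional genes (the abundant categories).
COG_LETTERS = tuple("CEFGHIJKLMPT")

#: Island lengths (genes) echoing a 15-island complement totalling 444.
DEFAULT_ISLAND_LENGTHS = (32, 46, 19, 38, 34, 40, 22, 33, 14, 12, 26, 39, 11, 14, 64)


class IslandSpec(NamedTuple):
    """A contiguous island block: order-index start, length in genes, the
    clade carrying it, and the (negative) GC offset of its genes."""

    start: int
    length: int
    clade: int
    gc_shift: float = -0.05


def default_island_specs(
    n_genes: int = 5635,
    n_clades: int = 7,
    lengths=DEFAULT_ISLAND_LENGTHS,
    gc_shift: float = -0.05,
) -> tuple[IslandSpec, ...]:
    """Evenly spaced island blocks cycling over clades."""
    total = sum(lengths)
    gap = (n_genes - total) // (len(lengths) + 1)
    if gap < 1:
        raise ConfigError("n_genes too small for the island complement")
    specs = []
    pos = gap
    for i, length in enumerate(lengths):
        specs.append(IslandSpec(pos, length, i % n_clades, gc_shift))
        pos += length + gap
    return tuple(specs)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic strain collection.

    Defaults mirror the emulated study design: 46 strains in 7 clades,
    5,635 array-targeted genes probed by up to 7 probes each plus 720
    negative controls, a core-genome GC mean of 47.6%, and 15 clade-linked
    island blocks with depressed GC.
    """

    n_strains: int = 46
    clade_sizes: tuple = (12, 10, 8, 6, 5, 3, 2)
    n_genes: int = 5635
    n_core_genes: int = 3400
    probes_per_gene: int = 7
    n_control_probes: int = 720
    island_specs: tuple = ()
    core_gc_mean: float = 0.476
    gc_sd: float = 0.03
    category_probs: tuple = (0.55, 0.30, 0.15)  # functional, hypothetical, MGE
    present_signal_mean: float = 8.0  # natural-log-scale intensity params
    present_signal_sd: float = 0.35
    absent_signal_mean: float = 5.7
    absent_signal_sd: float = 0.35
    control_signal_mean: float = 5.7
    mlst_length: int = 3000
    mlst_mutation_rate: float = 1.0
    clade_depth_range: tuple = (0.008, 0.025)
    strain_depth: float = 0.002
    turnover_rate: float = 0.02
    background_aux_presence: float = 0.5
    gain_loss_rate: float = 20.0
    divergent_clade: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.island_specs:
            self.island_specs = default_island_specs(self.n_genes, len(self.clade_sizes))
        self.island_specs = tuple(IslandSpec(*s) for s in self.island_specs)

    def validate(self) -> "SimulationConfig":
        if sum(self.clade_sizes) != self.n_strains:
            raise ConfigError("clade_sizes must sum to n_strains")
        if any(c < 1 for c in self.clade_sizes):
            raise ConfigError("clade sizes must be positive")
        if self.n_core_genes > self.n_genes:
            raise ConfigError("n_core_genes must not exceed n_genes")
        if not 1 <= self.probes_per_gene <= 7:
            raise ConfigError("probes_per_gene must lie in 1..7")
        total_island = sum(s.length for s in self.island_specs)
        if self.n_core_genes + total_island > self.n_genes:
            raise ConfigError("core plus island genes exceed n_genes")
        spans = sorted((s.start, s.start + s.length) for s in self.island_specs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ConfigError("island_specs ranges must be disjoint")
        if spans and (spans[0][0] < 0 or spans[-1][1] > self.n_genes):
            raise ConfigError("island_specs ranges must lie within [0, n_genes)")
        for s in self.island_specs:
            if not 0 <= s.clade < len(self.clade_sizes):
                raise ConfigError("island clade assignment out of range")
        probs = (
            self.background_aux_presence,
            self.turnover_rate,
            *self.category_probs,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ConfigError("category_probs must sum to 1")
        if self.gain_loss_rate < 0:
            raise ConfigError("gain_loss_rate must be non-negative")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("clade_sizes", "category_probs", "clade_depth_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "island_specs" in data:
            data["island_specs"] = tuple(IslandSpec(*s) for s in data["island_specs"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["island_specs"] = [list(s) for s in self.island_specs]
        for key in ("clade_sizes", "category_probs", "clade_depth_range"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    pa_truth: PresenceAbsenceMatrix
    clade_of: pd.Series
    tree: TreeNode
    tree_newick: str
    island_truth: list = field(default_factory=list)
    mlst_seqs: dict = field(default_factory=dict)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _evolve(parent: np.ndarray, branch: float, rate: float, rng) -> np.ndarray:
    """One Jukes-Cantor-style step: each site substitutes with probability
    1 - exp(-rate * branch), to a uniformly chosen different base."""
    child = parent.copy()
    hit = rng.random(parent.size) < -np.expm1(-rate * branch)
    if hit.any():
        child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return child


def simulate_collection(
    config: SimulationConfig,
) -> tuple[ProbeSignalMatrix, pd.DataFrame, GroundTruth]:
    """Generate (probe signal matrix, gene annotations, ground truth).

    Deterministic given ``config.seed``; see the module docstring for the
    generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_clades = len(config.clade_sizes)
    clade_labels = [string.ascii_uppercase[i % 26] for i in range(n_clades)]

    strains = [f"ST{i + 1:02d}" for i in range(config.n_strains)]
    clade_of = pd.Series(
        np.repeat(clade_labels, config.clade_sizes), index=strains, name="clade"
    )
    clade_idx = np.repeat(np.arange(n_clades), config.clade_sizes)

    lo, hi = config.clade_depth_range
    clade_depths = rng.uniform(lo, hi, size=n_clades)
    if config.divergent_clade and n_clades >= 2:
        # the content outlier is also the phylogenetically outermost clade,
        # keeping the content-vs-relatedness association monotone
        clade_depths[-1] = 1.5 * hi

    # ---- gene pool layout along the reference chromosome -----------------
    loci = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    island_pos = np.zeros(config.n_genes, dtype=bool)
    island_of = np.full(config.n_genes, -1)
    gc_shift_of = np.zeros(config.n_genes)
    for k, spec in enumerate(config.island_specs):
        sl = slice(spec.start, spec.start + spec.length)
        island_pos[sl] = True
        island_of[sl] = k
        gc_shift_of[sl] = spec.gc_shift

    non_island = np.where(~island_pos)[0]
    core_pos_idx = rng.choice(non_island, size=config.n_core_genes, replace=False)
    is_core = np.zeros(config.n_genes, dtype=bool)
    is_core[core_pos_idx] = True
    is_bg_aux = ~is_core & ~island_pos

    # ---- categories, GC, COG letters ------------------------------------
    category = np.full(config.n_genes, CATEGORY_FUNCTIONAL, dtype=object)
    aux_idx = np.where(~is_core)[0]
    draws = rng.choice(3, size=aux_idx.size, p=list(config.category_probs))
    category[aux_idx] = np.array(
        [CATEGORY_FUNCTIONAL, CATEGORY_HYPOTHETICAL, CATEGORY_MGE], dtype=object
    )[draws]

    gc = rng.normal(config.core_gc_mean + gc_shift_of, config.gc_sd)
    gc = np.clip(gc, 0.2, 0.8)

    cog = np.full(config.n_genes, None, dtype=object)
    functional = category == CATEGORY_FUNCTIONAL
    cog[functional] = rng.choice(COG_LETTERS, size=int(functional.sum()))

    annotations = pd.DataFrame(
        {
            "order_index": np.arange(config.n_genes),
            "gc": gc,
            "category": category,
            "cog": cog,
        },
        index=pd.Index(loci, name="locus_tag"),
    )

    # ---- ground-truth presence/absence ----------------------------------
    presence = np.zeros((config.n_genes, config.n_strains), dtype=bool)
    presence[is_core] = True
    for k, spec in enumerate(config.island_specs):
        presence[island_of == k] = (clade_idx == spec.clade)[None, :]

    # background-gene presence evolves along the clade tree: a root state
    # (Bernoulli background_aux_presence) toggled on each clade branch with
    # probability 1 - exp(-gain_loss_rate * depth), so closer clades share
    # more background content
    bg_idx = np.where(is_bg_aux)[0]
    p_flip = -np.expm1(-config.gain_loss_rate * clade_depths)
    root_state = rng.random(bg_idx.size) < config.background_aux_presence
    branch_flips = rng.random((bg_idx.size, n_clades)) < p_flip[None, :]
    clade_pattern = root_state[:, None] ^ branch_flips
    if config.divergent_clade and n_clades >= 2:
        # outlier clade: complement of the first clade's background pattern,
        # stretching the similarity gradient down toward its closed-format
        # floor (an analogue of a collection's most distant isolate)
        clade_pattern[:, -1] = ~clade_pattern[:, 0]
    universal = clade_pattern.all(axis=1)
    if universal.any():  # keep background genes truly auxiliary
        drop = rng.integers(0, n_clades, size=int(universal.sum()))
        clade_pattern[np.where(universal)[0], drop] = False
    presence[bg_idx] = clade_pattern[:, clade_idx]

    pool = is_bg_aux & (
        (category == CATEGORY_HYPOTHETICAL) | (category == CATEGORY_MGE)
    )
    flips = rng.random((int(pool.sum()), config.n_strains)) < config.turnover_rate
    presence[pool] ^= flips
    # turnover may promote a pool gene to universal presence; demote it
    pool_rows = np.where(pool)[0]
    universal_rows = pool_rows[presence[pool_rows].all(axis=1)]
    if universal_rows.size:
        cols = rng.integers(0, config.n_strains, size=universal_rows.size)
        presence[universal_rows, cols] = False

    pa_truth = PresenceAbsenceMatrix(
        pd.DataFrame(presence, index=annotations.index, columns=strains)
    )

    # ---- probe signals ---------------------------------------------------
    reps = np.repeat(np.arange(config.n_genes), config.probes_per_gene)
    probe_ids = [
        f"{loci[g]}_p{j + 1}"
        for g in range(config.n_genes)
        for j in range(config.probes_per_gene)
    ]
    present_rep = presence[reps]
    log_mean = np.where(
        present_rep, config.present_signal_mean, config.absent_signal_mean
    )
    log_sd = np.where(present_rep, config.present_signal_sd, config.absent_signal_sd)
    gene_signals = np.exp(log_mean + log_sd * rng.standard_normal(present_rep.shape))

    control_ids = [f"CTRL{j + 1:04d}" for j in range(config.n_control_probes)]
    control_signals = np.exp(
        config.control_signal_mean
        + config.absent_signal_sd
        * rng.standard_normal((config.n_control_probes, config.n_strains))
    )

    values = pd.DataFrame(
        np.vstack([gene_signals, control_signals]),
        index=pd.Index(probe_ids + control_ids, name="probe_id"),
        columns=strains,
    )
    probe_to_gene = pd.Series(loci[reps], index=probe_ids, name="locus_tag")
    probe_matrix = ProbeSignalMatrix(values, probe_to_gene, frozenset(control_ids))

    # ---- clade tree and MLST sequences ----------------------------------
    root_seq = rng.integers(0, 4, size=config.mlst_length)
    mlst_seqs: dict[str, str] = {}
    clade_parts = []
    for ci, label in enumerate(clade_labels):
        clade_seq = _evolve(root_seq, clade_depths[ci], config.mlst_mutation_rate, rng)
        members = [s for s, c in clade_of.items() if c == label]
        leaves = []
        for s in members:
            seq = _evolve(clade_seq, config.strain_depth, config.mlst_mutation_rate, rng)
            mlst_seqs[s] = "".join(_BASES[seq].tobytes().decode())
            leaves.append(f"{s}:{config.strain_depth}")
        clade_parts.append(f"({','.join(leaves)}){label}:{clade_depths[ci]:.6f}")
    newick = f"({','.join(clade_parts)})root;"
    tree = TreeNode.read(_io.StringIO(newick))

    # ---- island ground truth --------------------------------------------
    island_truth = []
    for k, spec in enumerate(config.island_specs):
        members = list(loci[spec.start : spec.start + spec.length])
        isl = GenomicIsland(
            island_id=k + 1,
            start_locus=members[0],
            end_locus=members[-1],
            member_genes=members,
        )
        island_truth.append(island_stats(isl, annotations))

    truth = GroundTruth(
        pa_truth=pa_truth,
        clade_of=clade_of,
        tree=tree,
        tree_newick=newick,
        island_truth=island_truth,
        mlst_seqs=mlst_seqs,
    )
    return probe_matrix, annotations, truth


def emit_fixtures(
    probe_matrix: ProbeSignalMatrix,
    annotations: pd.DataFrame,
    truth: GroundTruth,
    outdir,
) -> dict[str, str]:
    """Write the simulated collection to plain-text files that round-trip
    through the package readers. Returns {name: path}."""
    from pathlib import Path

    from . import io as cio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": out / "probes.tsv",
        "probe_map": out / "probe_map.tsv",
        "annotations": out / "annotations.tsv",
        "mlst": out / "mlst.fasta",
        "pa_truth": out / "pa_truth.tsv",
        "clades": out / "clades.tsv",
        "islands_truth": out / "islands_truth.tsv",
        "tree": out / "tree.nwk",
    }
    cio.write_probe_matrix(probe_matrix, paths["probes"])
    cio.write_probe_map(probe_matrix, paths["probe_map"])
    cio.write_annotations(annotations, paths["annotations"])
    cio.write_mlst_fasta(truth.mlst_seqs, paths["mlst"])
    cio.write_pa_matrix(truth.pa_truth, paths["pa_truth"])
    truth.clade_of.rename_axis("strain").to_csv(paths["clades"], sep="\t")
    from .islands import islands_table

    islands_table(truth.island_truth).to_csv(paths["islands_truth"], sep="\t", index=False)
    with open(paths["tree"], "w") as fh:
        fh.write(truth.tree_newick + "\n")
    return {k: str(v) for k, v in paths.items()}
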