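"""End-to-end analysis: simulated collection -> calls -> all summaries.

`run_full_analysis` chains every stage of the pipeline on a synthetic
strain collection — probe normalization and presence calling validated
against reference-strain truth, soft-core/rarefaction/power-law analysis,
island detection with GC and congruence statistics, divergence
decomposition against MLST identity, and tree/cluster construction — and
optionally writes the standard output files. It is the entry point used by
the examples and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, divergence, islands, pangenome, trees
from .simulate import GroundTruth, SimulationConfig, simulate_collection


@dataclass
class AnalysisResult:
    """Everything the pipeline computes on one collection."""

    config: SimulationConfig
    truth: GroundTruth
    annotations: pd.DataFrame
    cutoff: calling.CutoffResult
    calls: object
    per_strain_fdr: pd.Series
    soft_core: object
    prevalence: pd.Series
    rarefaction: pangenome.RarefactionResult
    power_law: pangenome.PowerLawFit
    islands: list
    island_gc: pd.DataFrame
    island_congruence: pd.DataFrame
    jaccard: pd.DataFrame
    identity: pd.DataFrame
    pairs: pd.DataFrame
    mantel: divergence.MantelResult
    divergence_pairs: pd.DataFrame
    divergence_bins: pd.DataFrame
    cog_pairs: pd.DataFrame
    cog_bins: pd.DataFrame
    tree: object
    support: pd.Series
    gene_groups: trees.GeneGroupAssignment
    reference_strains: list = field(default_factory=list)
    gene_signals: object = None


def default_reference_strains(truth: GroundTruth, n: int = 4) -> list[str]:
    """First strain of each of the first ``n`` clades — the synthetic
    counterpart of the study's four sequenced reference genomes."""
    refs = []
    for clade in truth.clade_of.unique():
        members = truth.clade_of.index[truth.clade_of == clade]
        refs.append(members[0])
        if len(refs) == n:
            break
    return refs


def run_full_analysis(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    outdir=None,
    n_boot: int = 100,
    rarefaction_reps: int = 100,
    congruence_permutations: int = 199,
    mantel_permutations: int = 999,
) -> AnalysisResult:
    """Run the whole pipeline on a synthetic collection.

    ``seed`` overrides ``config.seed`` and also feeds every stochastic
    downstream step (rarefaction sampling, permutation tests, bootstrap).
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = int(seed)
    probe_matrix, annotations, truth = simulate_collection(config)
    refs = default_reference_strains(truth)

    # presence/absence calling, validated on the reference strains
    normalized = calling.normalize_signals(probe_matrix)
    gene_signals = calling.summarize_gene_signals(normalized)
    ref_truth = truth.pa_truth.restrict_strains(refs)
    cutoff = calling.optimize_cutoff(gene_signals, ref_truth)
    calls = calling.call_presence(gene_signals, cutoff.cutoff)
    per_strain_fdr = calling.validate_fdr(calls, truth.pa_truth)

    # pan-genome
    prevalence = pangenome.gene_prevalence(calls)
    partition = pangenome.soft_core(calls)
    rarefaction = pangenome.core_rarefaction(
        calls, n_reps=rarefaction_reps, seed=config.seed, fixed_prefix=refs
    )
    power_law = pangenome.fit_power_law(rarefaction)

    # genomic islands along the reference order
    flags = islands.variable_flags(calls, partition.core, annotations)
    detected = [
        islands.island_stats(isl, annotations)
        for isl in islands.detect_islands(flags)
    ]
    island_gc = islands.island_gc_contrast(detected, partition.core, annotations)
    pa_aux = calls.restrict_genes(partition.auxiliary)
    congr_rows = []
    for isl in detected:
        members_in = [g for g in isl.member_genes if g in set(pa_aux.gene_ids)]
        if len(members_in) < 2:
            tau, p = np.nan, np.nan
        else:
            tau, p = islands.island_congruence(
                isl, pa_aux, n_permutations=congruence_permutations, seed=config.seed
            )
        congr_rows.append({"island_id": isl.island_id, "kendall_tau": tau, "p_value": p})
    congruence = pd.DataFrame(congr_rows)

    # divergence vs phylogeny
    jaccard = divergence.jaccard_matrix(calls)
    identity = divergence.mlst_identity_matrix(truth.mlst_seqs)
    pairs, mantel = divergence.content_vs_phylogeny(
        jaccard, identity, n_permutations=mantel_permutations, seed=config.seed
    )
    div_pairs, div_bins = divergence.decompose_divergence(calls, annotations, identity)
    cog_pairs, cog_bins = divergence.cog_divergence(calls, annotations, identity)

    # trees and clustering
    tree, support = trees.bootstrap_support(
        truth.mlst_seqs, n_boot=n_boot, seed=config.seed
    )
    aux_signals = gene_signals.values.loc[
        gene_signals.values.index.intersection(partition.auxiliary)
    ]
    gene_groups = trees.cluster_auxiliary_genes(aux_signals, n_groups=8)

    result = AnalysisResult(
        config=config,
        truth=truth,
        annotations=annotations,
        cutoff=cutoff,
        calls=calls,
        per_strain_fdr=per_strain_fdr,
        soft_core=partition,
        prevalence=prevalence,
        rarefaction=rarefaction,
        power_law=power_law,
        islands=detected,
        island_gc=island_gc,
        island_congruence=congruence,
        jaccard=jaccard,
        identity=identity,
        pairs=pairs,
        mantel=mantel,
        divergence_pairs=div_pairs,
        divergence_bins=div_bins,
        cog_pairs=cog_pairs,
        cog_bins=cog_bins,
        tree=tree,
        support=support,
        gene_groups=gene_groups,
        reference_strains=refs,
        gene_signals=gene_signals,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: AnalysisResult, outdir) -> dict[str, str]:
    """Write the pipeline's standard output files to ``outdir``."""
    from . import io as cio
    from .islands import islands_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, fn):
        paths[name] = str(out / name)
        fn(out / name)

    save("pa_calls.tsv", lambda p: cio.write_pa_matrix(result.calls, p))
    save("cutoff_report.json", lambda p: cio.write_cutoff_report(result.cutoff, p))
    save(
        "prevalence.tsv",
        lambda p: result.prevalence.rename_axis("locus_tag").to_csv(p, sep="\t"),
    )
    save(
        "rarefaction.tsv",
        lambda p: result.rarefaction.to_frame().to_csv(p, sep="\t", index=False),
    )
    save(
        "power_law.json",
        lambda p: Path(p).write_text(
            pd.Series(
                {
                    "a": result.power_law.a,
                    "b": result.power_law.b,
                    "c": result.power_law.c,
                    "hard_core": result.power_law.hard_core,
                    "rss": result.power_law.rss,
                }
            ).to_json(indent=2)
        ),
    )
    save("islands.tsv", lambda p: islands_table(result.islands).to_csv(p, sep="\t", index=False))
    save("island_gc.tsv", lambda p: result.island_gc.to_csv(p, sep="\t", index=False))
    save(
        "island_congruence.tsv",
        lambda p: result.island_congruence.to_csv(p, sep="\t", index=False),
    )
    save("jaccard.tsv", lambda p: cio.write_matrix_tsv(result.jaccard, p))
    save("mlst_identity.tsv", lambda p: cio.write_matrix_tsv(result.identity, p))
    save("pairs.tsv", lambda p: result.divergence_pairs.to_csv(p, sep="\t"))
    save(
        "divergence_bins.tsv",
        lambda p: result.divergence_bins.to_csv(p, sep="\t", index=False),
    )
    save("cog_bins.tsv", lambda p: result.cog_bins.to_csv(p, sep="\t", index=False))
    save(
        "gene_groups.tsv",
        lambda p: result.gene_groups.groups.rename_axis("locus_tag").to_csv(p, sep="\t"),
    )
    save("tree.nwk", lambda p: result.tree.write(str(p)))
    save(
        "jaccard.nex",
        lambda p: trees.export_nexus_distances(result.jaccard, p),
    )
    return paths
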