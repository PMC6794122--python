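"""Detect genomic islands and summarize their composition.

Flags auxiliary (variable) genes along the reference chromosomal order,
reports maximal runs of more than 10 consecutive variable genes as
islands, and computes each island's GC contrast against the core genome
plus the congruence of its strain-distribution pattern with the overall
auxiliary-gene pattern.
"""

from cghpan import (
    SimulationConfig,
    detect_islands,
    island_congruence,
    island_gc_contrast,
    island_stats,
    islands_table,
    simulate_collection,
    soft_core,
    variable_flags,
)

config = SimulationConfig(
    n_strains=18, clade_sizes=(6, 6, 4, 2), n_genes=900, n_core_genes=550,
    probes_per_gene=1, n_control_probes=40,
    island_specs=((120, 16, 0, -0.06), (400, 24, 1, -0.04), (700, 12, 2, -0.05)),
    seed=9,
)
_, annotations, truth = simulate_collection(config)
pa = truth.pa_truth

core, auxiliary = soft_core(pa)
flags = variable_flags(pa, core, annotations)
islands = [island_stats(isl, annotations) for isl in detect_islands(flags, min_run=11)]
print(islands_table(islands).to_string(index=False))

gc = island_gc_contrast(islands, core, annotations)
print("\nGC contrast vs core "
      f"(core mean {gc['core_gc_mean'].iloc[0]:.3f}):")
for _, row in gc.iterrows():
    print(f"  island {row['island_id']:.0f}: diff {row['gc_diff']:+.3f}, "
          f"p = {row['p_value']:.2e}")

pa_aux = pa.restrict_genes(auxiliary)
for isl in islands:
    tau, p = island_congruence(isl, pa_aux, n_permutations=199, seed=1)
    print(f"  island {isl.island_id} congruence with overall pattern: "
          f"tau = {tau:.2f}, p = {p:.3f}")
# Implanted islands show depressed GC (foreign origin signature); their
# clade-linked distribution is only weakly congruent with the overall
# auxiliary gene pattern, as expected for horizontally acquired blocks.
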