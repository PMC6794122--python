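"""Generate a synthetic CGH strain collection and write its files.

Builds a small clade-structured collection with two implanted genomic
islands, prints what the ground truth contains, and emits the plain-text
fixture files (probe matrix, probe map, annotations, MLST FASTA, truth
tables) that the rest of the pipeline consumes.
"""

from cghpan import SimulationConfig, emit_fixtures, simulate_collection

config = SimulationConfig(
    n_strains=12,
    clade_sizes=(4, 4, 2, 2),
    n_genes=600,
    n_core_genes=380,
    probes_per_gene=3,
    n_control_probes=50,
    island_specs=((80, 15, 0, -0.05), (300, 20, 1, -0.05)),
    seed=7,
)
probe_matrix, annotations, truth = simulate_collection(config)

print(f"strains: {config.n_strains} in clades "
      f"{dict(truth.clade_of.value_counts())}")
print(f"probe matrix: {probe_matrix.values.shape[0]} probes "
      f"({len(probe_matrix.control_probes)} controls) x "
      f"{probe_matrix.values.shape[1]} strains")
print(f"true core genome: {truth.pa_truth.values.all(axis=1).sum()} genes "
      f"of {config.n_genes}")
for isl in truth.island_truth:
    print(f"  implanted island {isl.island_id}: {isl.size} genes "
          f"[{isl.start_locus}..{isl.end_locus}], GC {isl.gc_mean:.3f}")

paths = emit_fixtures(probe_matrix, annotations, truth, "scratch/example_collection")
print("files written:", ", ".join(sorted(paths)))
# The probe matrix holds log-normal intensities: bright for genes a strain
# carries, background-level otherwise; islands are clade-specific blocks.
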