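"""Soft core, core-genome rarefaction and the power-law hard core.

Partitions genes by prevalence (soft core = present in >90% of strains),
rarefies the strict-intersection core over random genome orderings with a
fixed reference prefix, and fits Y = a*X**b + c whose offset magnitude
|c| estimates the hard core of the whole species.
"""

from cghpan import (
    SimulationConfig,
    core_rarefaction,
    fit_power_law,
    gene_prevalence,
    simulate_collection,
    soft_core,
)
from cghpan.plotting import plot_rarefaction

config = SimulationConfig(
    n_strains=24, clade_sizes=(8, 6, 6, 4), n_genes=1500, n_core_genes=900,
    probes_per_gene=1, n_control_probes=40,
    island_specs=((150, 20, 0, -0.05), (600, 25, 1, -0.05), (1100, 30, 2, -0.05)),
    seed=3,
)
_, annotations, truth = simulate_collection(config)
pa = truth.pa_truth

prevalence = gene_prevalence(pa)
core, auxiliary = soft_core(pa, threshold=0.90)
print(f"soft core (>90% prevalence): {len(core)} of {config.n_genes} genes "
      f"({100 * len(core) / config.n_genes:.1f}%); auxiliary: {len(auxiliary)}")

rar = core_rarefaction(pa, n_reps=100, seed=3)
fit = fit_power_law(rar)
print(f"rarefaction: core shrinks {rar.means[0]:.0f} -> {rar.means[-1]:.0f} genes "
      f"over {config.n_strains} genomes")
print(f"power-law fit: Y = {fit.a:.1f} * X^{fit.b:.4f} {fit.c:+.1f}")
print(f"hard-core estimate |c| = {fit.hard_core:.0f} genes "
      f"(true simulated core: {config.n_core_genes})")
plot_rarefaction(rar, fit, "scratch/rarefaction.png")
print("plot written to scratch/rarefaction.png")
# The curve's asymptote is the gene set every genome of the species would
# share; the estimate should sit close to the simulated core size.
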