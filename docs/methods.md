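# Methods

## The analysis model

`cghpan` analyses gene content across an intraspecific bacterial strain
collection assayed on a closed-format CGH array. The pipeline's central
object is the genes × strains boolean presence/absence matrix; everything
upstream (probe normalization, per-gene summarization, cutoff calling)
exists to produce it with a validated error rate, and everything
downstream (core-genome estimation, island detection, divergence
decomposition, trees) consumes it. A closed-format assay can only see
genes present in the reference genomes the probes were designed from, so
all statements about the pan-genome are conditional on the reference gene
pool.

### Presence calling

Per strain column, the mean intensity of that array's negative-control
probes is subtracted from every spot and negatives are floored at 0
(intensities are physically non-negative). A gene's signal is the median
over its probes; the median is robust to a single failed or
cross-hybridizing probe. Presence is signal ≥ cutoff, with the boundary
counting as present (the conventional reading of a detection threshold).

The cutoff minimizes the pooled false-discovery rate over strains with
sequenced genomes, where a *discovery* is a presence call, FDR =
FP/(FP+TP). The grid is every distinct observed gene-signal value (the
FDR only changes at observed values, so the exact optimum lies on this
grid); ties break toward the smallest cutoff, which favours sensitivity.
The false-negative rate is reported alongside because minimizing FDR
alone says nothing about missed genes. Whether the published studies
pooled reference strains or averaged per strain is generally unstated;
pooling is the default and the per-strain table is always reported.

A caveat worth knowing: when the background (absent) signal distribution
has a lighter upper tail than the present distribution, the empirical
minimum FDR is attained degenerately at an extreme cutoff that calls
almost nothing (the largest observed signal is almost surely a present
gene). Interior optima — the regime the method is meant for — arise when
background artifacts have heavy tails, which is how the separation-ladder
test constructs its instances.

### Core genome

The soft core is the set of genes with prevalence strictly greater than
90% of strains ("more than 90%" read literally; the threshold is an
argument). Rarefaction draws genome orderings uniformly without
replacement (100 replicates by default), optionally fixing an initial
prefix to mimic a study design in which the sequenced references enter
first, and records the strict-intersection core size at each depth; the
strict intersection is the only reading under which the curve must be
non-increasing and converge to a "present in all genomes" hard core. The
power law Y = aX^b + c is fitted to the replicate means (the plotted bar
heights) by unconstrained nonlinear least squares with multi-start over
the exponent, and the hard core is reported as |c| with the sign of c
preserved in the output.

**Parameterization degeneracy.** Two branches of this family fit typical
rarefaction curves almost equally well: a decaying branch (a > 0, b < 0,
c > 0) whose asymptote c is the hard core, and a slowly-varying branch
(small |b|, offset c < 0 of no asymptotic meaning). Which branch attains
the lower residual is decided by small features of the early curve — a
fixed reference prefix, whose first points are a single genome order
rather than an average, often tips the balance to the shallow branch.
The fit is deliberately left unconstrained and the full parameter triple
is always reported so the branch is visible; |c| should be read as a
hard-core estimate only on the decaying branch.

### Genomic islands

A gene is *variable* iff it is auxiliary (outside the soft core).
Consecutiveness is measured over array-represented genes in reference
chromosomal order — loci absent from the array are invisible to CGH and
cannot interrupt a run. Islands are maximal runs of ≥ 11 variable genes
("more than 10"); `min_run` is an argument because a published
11-gene island under an "over 10" rule is consistent with either ≥ 10 or
≥ 11. Runs may be merged across at most `max_gap` interleaved core genes
(default 0). Island members are the variable genes of the span, so island
sizes always sum to the number of auxiliary genes inside detected spans.

Island statistics: GC mean ± sample SD over member genes; counts of
hypothetical and MGE-associated genes with their combined percentage
rounded half away from zero (matching how such tables are printed); a
two-sided Mann–Whitney test of member-gene GC against core-gene GC
(skipped below 3 genes); and a congruence statistic — Kendall's tau
between the vector of pairwise strain Jaccard distances restricted to the
island's genes and the same vector over all auxiliary genes, with a
Mantel-style permutation p-value (999 permutations, strain labels of the
island matrix permuted, one-sided greater). The congruence construction
is a documented stand-in: published island-vs-overall "Kendall
correlation" tables rarely state their exact construction.

### Divergence vs phylogenetic relatedness

Jaccard distance over present-gene sets is a metric; the matrix
implementation is checked against naive double loops and the triangle
inequality in the tests. MLST relatedness is raw pairwise identity of
equal-length concatenated housekeeping sequences (no model correction;
alignment is out of scope). The content–relatedness association uses
Spearman rank correlation between genomic similarity (1 − Jaccard) and
identity over unordered pairs, with a Mantel permutation p-value because
pairs sharing a strain are not independent.

Each pair's differing genes (symmetric difference) split into a pooled
hypothetical + MGE category versus functional genes; the two fractions
sum to 1 whenever the pair differs at all. Identity bins default to a
pooled < 0.95 bin plus 0.004-wide bins over [0.95, 1.0]; the
high-identity contrast bin starts at 0.982. Within a bin, the two
fractions are compared by a paired two-sided Wilcoxon signed-rank test
across pairs (the fractions are paired per strain pair); pairs are
treated as independent in this test, a simplification shared with the
analyses it emulates. Per-COG tallies use the same binning and rank COG
letters by mean differing-gene count per pair.

### Trees and clustering

Neighbor joining is scikit-bio's classic implementation (negative branch
estimates clamped to 0); on additive matrices it reproduces leaf-to-leaf
distances exactly, which the tests verify against closed forms. Bootstrap
support resamples alignment columns with replacement, rebuilds the
identity-distance NJ tree, and scores each internal bipartition of the
base tree; taxa are canonicalized by sorted name so support does not
depend on input order. The distance used per replicate is 1 − identity.
Gene groups come from average-linkage hierarchical clustering of
log2(signal + 1) profiles under Euclidean distance — the conventional
treatment for CGH heat maps — cut into 8 flat groups by default; metric,
linkage and group count are arguments.

## The synthetic generator

The generator emulates the design of a ~46-strain, 7-clade collection
probed on a 5,635-gene array (7 probes/gene, 720 negative controls).
Ground-truth gene content has four layers:

1. a universal core (default 3,400 genes; core GC mean 0.476, SD 0.03);
2. 15 contiguous island blocks (sizes echoing a published 444-gene
   complement) assigned to single clades, with GC offset −0.05;
3. background auxiliary genes whose presence evolves along the clade tree:
   a Bernoulli(0.5) root state toggled on each clade branch with
   probability 1 − exp(−gain_loss_rate · depth) (rate 20 per
   branch-length unit), so closer clades share more background content;
4. per-strain Bernoulli turnover (rate 0.02) restricted to the
   hypothetical/MGE background pool.

Layer 4 makes intra-clade gene differences hypothetical/MGE-dominated by
construction, and layers 2–3 (55% functional under the default category
probabilities 0.55/0.30/0.15) make inter-clade differences
functional-dominated — the qualitative pattern the divergence
decomposition is designed to detect. The last clade is an outlier: its
background pattern is the complement of the first clade's and its clade
branch is the longest, stretching pairwise genomic similarity down to its
closed-format floor (~64%) while keeping the content–relatedness
association monotone; with the default configuration the collection spans
~64–99% pairwise similarity with > 99% similarity within clades.

Probe intensities are log-normal — exp(N(8.0, 0.35)) for present
gene–strain pairs, exp(N(5.7, 0.35)) for absent pairs and controls, in
natural-log units — because one-channel arrays produce positive,
right-skewed signals. The defaults separate the two states cleanly
(optimized FDR ≈ 0): the generator deliberately does not model
cross-hybridization or probe thermodynamics, so it cannot reproduce the
few-percent FDRs of real arrays, and passing tests say nothing about
robustness to those artifacts. MLST sequences (3,000 bp, roughly seven
concatenated housekeeping loci) evolve by Jukes–Cantor-style per-site
substitution along the two-level clade tree (clade depths uniform in
[0.008, 0.025], strain branches 0.002), giving an identity gradient of
roughly 0.94–1.0. All randomness flows from one integer seed through a
single generator; identical configurations produce bit-identical output.

What the generator does **not** emulate: open pan-genomes (genes absent
from the references), recombination within MLST loci, probe-level
systematic biases (dye, spatial, print-tip), unbalanced probe counts per
gene, and island boundaries decorated with tRNA/integrase signatures.

## Problem sizes in the tests

Most tests run on scaled-down collections (12–24 strains, 400–1,500
genes, 1–3 probes/gene) chosen so the full suite completes in seconds
while leaving the statistical contrasts unambiguous; the end-to-end smoke
test and `scripts/acceptance.py` exercise the full 46 × 5,635 × 7 design.
The hard-core recovery check uses 24 strains and 100 rarefaction
replicates; the category-dominance check uses 20 seeded replicates of a
24-strain, 800-gene design; permutation tests default to 199–999
permutations depending on context.

## Known limitations

- The FDR criterion alone cannot distinguish a good cutoff from a
  degenerate high one when background tails are light; inspect the
  reported false-negative rate alongside.
- The hard-core estimate inherits the power-law branch ambiguity above;
  with few strains or a kinked prefix region the reported |c| may not be
  an asymptote.
- Identity bins with < 2 usable pairs skip the Wilcoxon contrast and are
  flagged rather than tested.
- The island congruence permutation permutes strain labels of the island
  matrix only, which is exact under the null of no association but does
  not model phylogenetic autocorrelation among strains.
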