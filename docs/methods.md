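# Methods

## Scope and data model

`pnatlas` analyzes stage-resolved single-cell RNA-seq of *Drosophila*
olfactory projection neurons (PNs): gene × cell count matrices with cell
annotations (stage, neuroblast lineage, optional type label and birth
rank). Counts enter as Matrix Market sparse files with gene/cell sidecars
or dense CSV; all computation happens on counts-per-million (CPM,
denominator = all genes in the matrix) and log2(CPM+1). Read alignment and
gene counting are upstream of this package.

## Quality control

Cells are kept when they have at least 100,000 reads ("fewer than" reads
strictly, so a cell at exactly 100,000 is retained) and when at least 2 of
the 6 pan-neuronal panel genes (*elav*, *brp*, *Syt1*, *nSyb*, *CadN*,
mCD8-GFP) reach 8 log2(CPM+1) (inclusive). For count-only data the read
total is the column sum; a `total_reads` metadata column is honored when
upstream mapping statistics exist. Both filters depend only on per-cell
statistics, so they are idempotent and order-independent.

## Feature selection

*Overdispersed genes*: dispersion = variance/mean of log2(CPM+1) per gene,
z-scored within 20 equal-occupancy mean bins; the top *n* (default 500)
are kept, ties broken by gene id so the ranking is deterministic and
order-free.

*Iterative marker discovery (ICIM-style)*: the published algorithm's
internals are not fully specified, so the package implements a documented
recursive variant: at each node, select overdispersed genes among the
current cells, split the cells in two by Ward clustering in that space,
keep all genes upregulated in either branch at BH-adjusted *p* < 0.01, and
accept the split (and recurse, to depth 8 or a 10-cell floor) only when at
least 5 genes pass. The output is the union over accepted splits. The
variant reproduces the algorithm's purpose — accumulating
type-distinguishing markers without supervision — with every choice
exposed as a parameter.

For cross-stage work the pipeline selects features **once over all
stages' cells** and reuses them at every stage
(`pipeline.run_cross_stage`). Markers are strongest mid-development;
features found there still carry type identity at stages where they are
weaker, and measured on synthetic data this raises off-peak clustering
accuracy (adult-stage ARI ~0.65 with per-stage selection vs ≥ 0.95 with a
shared set).

## Clustering

Density-based: HDBSCAN (scikit-learn implementation) on a 2-D embedding
(UMAP default, tSNE available; feature space pre-reduced to 30 PCs), noise
label −1, labels renumbered 0..k−1 by decreasing size. Graph-based: Leiden
(RB-configuration, resolution 1.0 by default) on the exact kNN graph
(k = 15, Euclidean metric in the 30-PC feature space). Noise cells are
excluded from signatures, matching and similarity statistics. Agreement
between the two routes is quantified by the adjusted Rand index.

## Differential expression and signatures

One-vs-rest Mann–Whitney U tests per cluster and gene. The scalar test
uses the exact U distribution for combined samples ≤ 20 without ties and
the tie/continuity-corrected normal approximation otherwise. The
one-vs-rest sweep exploits that the pooled sample is identical for every
cluster: genes are midranked once over all non-noise cells and each
cluster's U follows from its rank sum, with the tie term recovered from
the midrank-variance identity; results equal scipy's per-cluster tests to
1e-12 but cost one ranking pass instead of k. Benjamini–Hochberg
correction is applied within each cluster's gene family; signatures keep
upregulated genes at adjusted *p* strictly below 0.01. Stage-pair contrasts
rank genes by two-sided *p* (ties: |mean difference|, then gene id) and
keep the top 150 per pair.

## Cross-stage matching

Signature route: full Jaccard matrix between the two stages' signature
sets; a pair is `two_way` when the clusters are mutually most similar,
`one_way_*` when only one direction holds; argmax ties yield no match
(stringency), empty signatures are excluded, and `J(∅,∅) := 0` with a
warning. Marker route: a gene (or two-gene conjunction drawn from a
cluster's signature, capped at 200 genes) is *expressed in* a cluster when
≥ 50% of its cells sit at ≥ 4 log2(CPM+1); markers unique to one cluster
at both stages link those clusters when their majority lineages agree.
The expression threshold default (4) sits between the generator's marker
off state (~3.3 on this scale) and on state (≥ 5.4); it is config-exposed,
as no canonical numeric definition of "uniquely expressed" exists.
Inhibitory populations (vPN, APL) are excluded upstream when matching the
excitatory types. Only adjacent stage pairs are matched.

## Diversity

Cell level: each cell's mean inverse Euclidean distance to all other
cells of its (stage, lineage) subset; coincident pairs are excluded with a
warning. The default space is the shared feature set reduced to 30 PCs.
A 2-D layout per the visualization convention is available
(`embed_method="pca"|"umap"|"tsne"`), but measured on planted data planar
layouts scramble this statistic: neighbourhood embeddings equalize island
spacing (values flat across stages), and 2-PC projections are dominated by
whichever variance direction survives projection (the ordering can even
invert). In the denoised PC space, near-pair distances stay noise-bounded
and far-pair distances track expression distances, and the planted
diversity ordering is recovered in 12/12 lineage-seed checks; that is
therefore the default.

Cluster level: mean Pearson correlation between cluster centroids
restricted to one shared DE gene set — the signature union of the stage
whose clusters are most distinct (largest union) — with a percentile
bootstrap 95% CI over cluster pairs (1000 draws). Using per-stage DE sets
instead makes correlations incomparable across stages.

## Birth-order covariation

Type centroids are computed in PC space (PCA over all genes detected in
the subset; min(20, n_types−1) components) and correlated; rows are
ordered by birth rank. For each type *X*, the earlier- or later-born group
with more types is selected (tie → earlier); *X* is skipped when the group
has fewer than 5 types. Spearman ρ is computed between correlation-with-*X*
and *negative* birth distance, so positive ρ means nearer-born ⇒ more
similar; the statistic is the average ρ over eligible types. The
permutation test shuffles birth ranks uniformly (default 5000 iterations)
and reports *p* = #(ρ_perm > ρ_obs)/N — strictly greater, so *p* can be
exactly 0; a (k+1)/(N+1) estimator is available behind a flag. A full
enumeration of the null is provided for small type counts and is used to
validate the sampled test.

## Dynamics

The dynamic-gene union pools the top-150 stage-pair DE genes over all
unordered stage pairs. Per-gene per-stage median log2(CPM+1) profiles are
normalized by their maximum (all-zero genes excluded with a warning),
embedded in 2-D (tSNE) and density-clustered; genes left unassigned become
singleton groups. Each group's mean profile is classified: `up` when
last ≥ first + 0.2 (normalized units) and the steps are monotone allowing
one counter-step ≤ 0.05; `down` symmetric; otherwise `none`. The δ and
tolerance are config-exposed — the grouping-then-trend structure mirrors
how such profiles are read by eye, but a concrete rule is needed for a
testable artifact.

## Dendrograms

Complete-linkage (farthest-point) hierarchical clustering on Euclidean
centroid distances, with optimal leaf ordering (successive-leaf distance
sum minimized); input rows are canonicalized by label before linkage so
the result is row-order invariant. Trees are exportable as Newick.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- 4 ordered stages; lineages adPN (15 types), lPN (10), vPN (3), APL (1);
  30 cells per type per stage (3480 cells, 870/stage); 5000 genes.
- Counts are negative binomial (gamma–Poisson, shared shape r = 10,
  typical of deep SMART-seq2 plates). A cell's expected expression is the
  softmax of per-gene baselines plus additive log-scale effects, times a
  log-normal library size (median 500k, σ_ln = 0.7 — ~1% of cells fall
  below the 100k QC cut). CPM semantics are exact by construction.
- Gene baselines are log-normal (σ_ln = 1.5). The six QC panel genes sit
  high (ln-mean 3) so genuine neurons pass the marker filter.
- **Type markers**: 10 per type, drawn from a low off-state baseline
  (ln-mean −2, i.e. ~9 CPM) and elevated in their own type by
  4.5 log2 × schedule (0.6, 1.0, 0.8, 0.5) — near on/off at the peak
  stage, ~4.8-fold at the adult trough. The schedule makes separability
  peak at the second stage while every stage stays resolvable, which the
  cross-stage matching task requires.
- **Stage programs**: 150 down-regulated genes in five monotone
  sub-profiles and 60 up-regulated in two, amplitude 3 log2 across the
  time course.
- **Pruning module**: 20 genes, +2 log2 in embryonic-born adPN types
  (first 30% of the lineage) at the first stage only.
- **Birth-order gradients**: 15 genes, ±0.15 log2 per birth-rank step
  (sign alternating), attenuation (1.0, 0.6, 0.0, 0.0) — present early,
  gone by the third stage. Pruning and gradient amplitudes are kept
  subordinate to the type-effect schedule so that within-stage diversity
  peaks at the second stage rather than at the first.
- **Neurotransmitter programs**: 2 genes per class (cholinergic for
  adPN/lPN, GABA for APL, glutamate for vPN), carried at all stages and
  doubled at the adult stage.

What it does **not** model: batch/plate effects, doublets, cell-cycle
structure, zero inflation beyond the NB, per-gene dispersion variation,
and within-type substructure. Passing tests therefore demonstrate that the
algorithms recover structure of the planted kinds at realistic effect
sizes and depths — not that they would survive batch confounding or
shallow-coverage data.

## Determinism and numerics

Every stochastic step takes an explicit seed (numpy Generator, UMAP/tSNE
`random_state`, Leiden seed); tabular outputs use fixed float formatting
(`%.6g`) and sorted JSON keys, so identical config + seed reproduces
output files byte for byte. Ties are broken lexicographically by gene id
throughout. Degenerate inputs (all-zero cells, constant centroids,
coincident embedding points, single-value bootstraps) warn and continue
rather than raise, except where a contract is violated (empty samples,
mismatched lengths, invalid parameters).

## Problem sizes used in validation

The test suite exercises the default study conditions (5000 × 3480) over
ten generator seeds for clustering, matching, diversity and dynamics;
birth-order power uses 20 first-stage replicates and calibration 50
adult-stage replicates with 1000 permutation iterations (the package
default remains 5000, the convention for reported analyses); unit tests
run on scaled-down configurations of the same generator.
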