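# pnatlas

Stage-resolved single-cell transcriptome analysis of developing *Drosophila*
olfactory projection neurons (PNs), packaged as a reusable, tested pipeline.

Olfactory PNs acquire ~50 glomerulus-specific identities from two excitatory
neuroblast lineages (anterodorsal, adPN; lateral, lPN) plus smaller
inhibitory populations (ventral PNs and the APL neuron). Over metamorphosis
— 0 h, 24 h, 48 h after puparium formation (APF) and adulthood — their
transcriptomes change dramatically: type distinctions are sharpest during
circuit assembly (~24 h APF) and fade as neurons mature, which makes it
hard to decide which cluster at one stage corresponds to which at the
next. `pnatlas` implements the analysis toolkit for this problem:

- **Preprocessing** — cells need ≥ 100,000 reads and ≥ 8 log2(CPM+1) in at
  least 2 of 6 pan-neuronal markers (*elav*, *brp*, *Syt1*, *nSyb*, *CadN*,
  mCD8-GFP); expression is CPM-normalized and analyzed as log2(CPM+1).
- **Feature selection** — overdispersed genes (variance/mean z-scored in
  mean bins), and an iterative-clustering marker discovery (ICIM-style)
  routine that recursively bipartitions cells and accumulates genes that
  significantly distinguish the branches.
- **Clustering** — HDBSCAN on a 2-D embedding, or Leiden on the kNN graph,
  behind one interface, with the adjusted Rand index (ARI) to compare them.
- **Differential expression** — one-vs-rest Mann–Whitney U tests per
  cluster with Benjamini–Hochberg correction; genes at adjusted *p* < 0.01
  upregulated in a cluster form its *signature set*.
- **Cross-stage matching** — clusters at adjacent stages are matched when
  they are reciprocal best hits under the Jaccard similarity
  *J(A,B) = |A∩B| / |A∪B|* of their signature sets, and independently via
  single genes or two-gene combinations uniquely expressed in one cluster
  per stage (with lineage consistency).
- **Diversity** — per (stage, lineage): each cell's mean inverse Euclidean
  distance to the other cells (cell level), and the mean Pearson
  correlation between cluster centroids on a shared DE gene set with
  bootstrap 95% CIs (cluster level).
- **Birth order** — PN types are born in a stereotyped sequence. For each
  type *X*, the larger of its earlier-/later-born groups (≥ 5 types) is
  ranked by correlation with *X* and by birth distance; the average
  Spearman ρ across types is tested against a permutation null (birth
  order shuffled, *p* = #(ρ_perm > ρ_obs)/N).
- **Dynamics** — the union of the top-150 stage-pair DE genes is profiled
  (per-stage medians, max-normalized to 1), grouped by profile shape, and
  classified as monotone up / down / trendless.
- **Synthetic data** — a negative-binomial generator that plants all of the
  above structure (type markers peaking at the second stage, monotone stage
  programs, a pruning module in embryonic-born adPNs at 0 h, decaying
  birth-order gradients, neurotransmitter programs) with full ground truth,
  so every stage of the pipeline is testable without downloads.

## Worked example

```python
import pnatlas as pa
from pnatlas import pipeline

dataset, truth = pa.simulate(pa.SimConfig(seed=0))      # 5000 genes x 3480 cells
config = pa.PipelineConfig(seed=0)
dataset = pipeline.preprocess_all(dataset, config)       # QC + CPM + marker filter
analyses = pipeline.run_cross_stage(dataset, config)     # cluster every stage
for match in pipeline.adjacent_stage_matches(analyses, dataset.stage_order):
    print(match.stage_a, match.stage_b, "two-way matches:", len(match.two_way()))
```

prints

```
P0 P24 two-way matches: 25
P24 P48 two-way matches: 25
P48 Adult two-way matches: 24
```

— of the 25 planted excitatory types, 24–25 are recovered per adjacent
stage pair as reciprocal-best Jaccard matches (the remainder reflect
clusters merged at the weakest stages). The birth-order test on the same
data:

```python
sub = dataset.subset_stage("P0").subset_lineage("adPN")
corr, ranks = pa.type_correlation_matrix(sub)
res = pa.birth_order_permutation(corr, ranks, n_iter=1000, seed=0)
print(f"observed rho {res.observed:.3f}, p = {res.p_value}")
```

```
observed rho 0.561, p = 0.0
```

— at 0 h APF, types born closer together are markedly more similar
(average Spearman ρ ≈ 0.56; no permutation exceeded it), while the same
test on adult data accepts the null, mirroring the decay of the planted
gradient.

## Command line

Every step is also a subcommand of the `pnatlas` console script
(`simulate`, `qc`, `features`, `cluster`, `de`, `match`, `diversity`,
`birthorder`, `dynamics`, `report`) with global `--config`, `--seed` and
`--log-level` flags; outputs are TSV/JSON with deterministic formatting,
so reruns with the same config and seed are byte-identical. See
`pnatlas --help`.

## Documentation

The model assumptions, parameter choices and known limitations are
documented in [docs/methods.md](docs/methods.md).
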