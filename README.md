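# regulonscan

Ranking-and-recovery inference of transcription-factor (TF) regulons from a
set of co-expressed genes.

Given an input gene set, `regulonscan` detects which TF binding motifs (and
which ChIP peak tracks) are enriched among the regulatory regions of those
genes, selects the optimal subset of direct target genes for each enriched
feature, and maps enriched motifs to candidate TFs through an association
graph of motif annotations, TF homology and motif similarity. It is aimed at
computational biologists reverse-engineering the regulatory network behind a
co-expression signature, and it ships a synthetic-data generator so the
whole pipeline can be exercised and validated without any external genome
data.

## The method

**Offline ranking.** For each motif in a PWM collection, every gene's
regulatory search space (500 bp upstream of the TSS, or 10/20 kb around it,
truncated at neighbouring genes, coding exons excluded) is scanned for
*homotypic clusters* of binding sites with a two-state generative model:
sites of the motif, on either strand, separated by geometric background
gaps. The region score is the log-likelihood ratio

```
score = log2 [ P(sequence | site cluster) / P(sequence | background) ]
```

maximised exactly over site placements by dynamic programming. Regions are
ranked per species, and the per-species rank ratios r_(1) <= ... <= r_(K) of
each gene are aggregated with order statistics,

```
Q = K! * V_K,   V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(K-k+1)^i / i!
```

the probability of ranks at least that good across K species by chance.
Genes are ordered by ascending Q; genes scoring zero everywhere are queued
randomly at the end. ChIP tracks are ranked analogously by the maximum peak
`signalValue` over each gene's regions. The result is a *ranking database*:
one total ordering of the gene universe per feature.

**Recovery.** For an input set of s genes, the recovery curve c(k) counts
members at rank <= k. Enrichment is the area under that curve in the top
fraction (default 3%) of the ranking, `AUC = sum_{k<=T} c(k) / (T*s)`,
z-scored across all features of a collection into a normalized enrichment
score, `NES = (AUC - mean) / sd` (motifs and tracks are normalized
separately). Features with NES >= 3.0 are reported. Their direct targets
are the input genes ranked above the *leading edge*: the rank where the
feature's recovery maximally exceeds the collection background
(mean + 2 SD of all recovery curves).

**motif2TF.** Enriched motifs are linked to TFs over a typed graph —
annotation edges (motif to TF, possibly of another species), homology edges
(percent identity), similarity edges (p-value) — using paths with one
annotation edge, at most one similarity edge and at most one homology edge.
Candidates are tiered: directly annotated TFs, then TFs encoded by input
genes, then homologs, then similarity-derived TFs; within a tier the
shortest, best-evidenced path wins. Per-TF *regulons* merge the targets of
all features mapped to a TF, and batches of analyses aggregate into
*meta-regulons* with per-target recurrence counts.

## A worked example

```python
from regulonscan import (SimulationConfig, simulate_dataset,
                         build_motif_database, run_enrichment, RecoveryParams)

cfg = SimulationConfig(seed=3, n_genes=500, n_target_genes=15,
                       n_decoy_pwms=30, n_species=3,
                       noise_fractions=(0.25,), set_size=20)
ds = simulate_dataset(cfg)                       # sequences, PWMs, truth
db = build_motif_database(ds.sequences, ds.pwms, ds.universe, seed=3)
results = run_enrichment(db, ds.gene_sets[0.25],
                         RecoveryParams(top_fraction=0.03, nes_threshold=3.0,
                                        rank_threshold=500))
for r in results:
    print(r.feature_id, round(r.auc, 3), round(r.nes, 2),
          r.leading_edge_rank, len(r.candidate_targets))
```

prints

```
true_motif 0.363 4.7 16 12
```

the planted motif is the only feature passing NES >= 3 (NES 4.70): its
recovery AUC in the top 3% of the 500-gene ranking is 0.363, the leading
edge falls at rank 16, and the 12 input genes above it — all planted
targets, none of the 5 noise genes — are reported as its direct targets.
The `examples/` directory walks through every capability the same way
(delineation, scanning, ranking, enrichment, motif2TF, regulons,
noise robustness), and the `regulonscan` command exposes the stages as
`simulate / delineate / scan / build-db / enrich / map-tf / regulons /
meta / run` subcommands, each writing a JSON run manifest.

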