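"""Recovery-curve enrichment of a gene set, with leading-edge targets.

Runs the full motif enrichment on a simulated input set (planted targets
plus noise) and prints the reported features with their AUC, NES and
selected direct targets.
"""

from regulonscan import (RecoveryParams, SimulationConfig,
                         build_motif_database, run_enrichment,
                         simulate_dataset)

cfg = SimulationConfig(seed=3, n_genes=500, n_target_genes=15,
                       n_decoy_pwms=30, n_species=3,
                       noise_fractions=(0.25,), set_size=20)
ds = simulate_dataset(cfg)
db = build_motif_database(ds.sequences, ds.pwms, ds.universe, seed=3)

gene_set = ds.gene_sets[0.25]  # 15 true targets + 5 noise genes
params = RecoveryParams(top_fraction=0.03, nes_threshold=3.0,
                        rank_threshold=500)
results = run_enrichment(db, gene_set, params)

print(f"input set: {len(gene_set)} genes (25% noise); "
      f"{len(results)} feature(s) with NES >= {params.nes_threshold}\n")
truth = set(ds.target_genes)
for res in results:
    targets = res.target_genes
    tp = len(set(targets) & truth)
    print(f"{res.feature_id:>12}: AUC={res.auc:.3f} NES={res.nes:.2f} "
          f"leading edge k*={res.leading_edge_rank} "
          f"targets={len(targets)} ({tp} planted)")

print("""
The AUC measures how early the input genes are recovered in the top 3% of
the motif's genome ranking; the NES is that AUC z-scored against all motifs
of the collection. Targets are the input genes ranked above the leading
edge, where the recovery curve maximally exceeds the collection background
(mean + 2 SD) — noise genes, ranked like background, are excluded.""")
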