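"""Build a whole-universe ranking database from a simulated study.

Simulates a small multi-species dataset with one planted motif, scans every
region with every PWM, aggregates the per-species rankings with order
statistics, and shows where the planted target genes land in the true
motif's final ranking.
"""

from regulonscan import (SimulationConfig, aggregate_species_ranks,
                         build_motif_database, simulate_dataset)

cfg = SimulationConfig(seed=0, n_genes=200, n_target_genes=10,
                       n_decoy_pwms=10, n_species=3)
ds = simulate_dataset(cfg)
db = build_motif_database(ds.sequences, ds.pwms, ds.universe, seed=0)

print(f"database: {db.n_genes} genes x {len(db.features)} motifs "
      f"({cfg.n_species} species aggregated)")

column = db.column("true_motif")
target_ranks = sorted(int(column[ds.universe.index(g)])
                      for g in ds.target_genes)
print(f"ranks of the 10 planted target genes under the true motif: "
      f"{target_ranks}")

q_good = aggregate_species_ranks([0.01, 0.02, 0.03])
q_mixed = aggregate_species_ranks([0.01, 0.5, 0.9])
print(f"\norder-statistic q-value, consistently top gene:   {q_good:.2e}")
print(f"order-statistic q-value, top in one species only: {q_mixed:.2e}")

print("""
Planted genes occupy the first ranks because their cluster scores are high
in *every* species: the order-statistic q-value rewards cross-species
consistency, and genes scoring zero everywhere are queued randomly at the
bottom.""")
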