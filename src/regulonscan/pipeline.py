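"""End-to-end composition: scan -> rank -> recover -> map -> assemble.

These helpers wire the stage modules together for the common case of a
:class:`~regulonscan.synthetic.SyntheticDataset` or equivalent in-memory
inputs.  The planted-signal and noise-robustness experiments used for
validation live here too, so tests, scripts and examples share one code
path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crm import CrmScoreParams, scan_sequences
from .pwm import PWM
from .ranking import (RankingDatabase, build_database, build_track_ranking,
                      rank_genes_from_species_scores)
from .recovery import EnrichmentResult, RecoveryParams, run_enrichment
from .search_space import Region
from .synthetic import (SimulationConfig, SyntheticDataset, TRUE_MOTIF_ID,
                        simulate_dataset)

log = logging.getLogger(__name__)


def score_regions(
    sequences: dict[str, str],
    pwms: list[PWM],
    params: CrmScoreParams | None = None,
) -> pd.DataFrame:
    """Score a keyed region FASTA (``gene|region|species``) with a PWM
    collection; returns a long table (motif_id, gene_id, region, species,
    score)."""
    keys = sorted(sequences)
    scores = scan_sequences([sequences[k] for k in keys], pwms, params)
    rows = []
    for i, key in enumerate(keys):
        gene_id, region, species = key.split("|")
        for m, pwm in enumerate(pwms):
            rows.append((pwm.motif_id, gene_id, int(region), species,
                         scores[i, m]))
    return pd.DataFrame(rows, columns=[
        "motif_id", "gene_id", "region", "species_id", "score"])


def build_motif_database(
    species_sequences: dict[str, dict[str, str]],
    pwms: list[PWM],
    universe: list[str],
    seed: int,
    crm_params: CrmScoreParams | None = None,
    collection: str = "motifs",
) -> RankingDatabase:
    """Scan every species' regions with every PWM and aggregate into one
    ranking database (one column per motif)."""
    gene_index = {g: i for i, g in enumerate(universe)}
    G = len(universe)
    species_list = sorted(species_sequences)
    n_pwms = len(pwms)
    # best region score per (species, gene, pwm); NaN = gene absent
    best = np.full((len(species_list), G, n_pwms), np.nan)
    for s, species in enumerate(species_list):
        seqs = species_sequences[species]
        keys = sorted(seqs)
        scores = scan_sequences([seqs[k] for k in keys], pwms, crm_params)
        for i, key in enumerate(keys):
            gene_id = key.split("|")[0]
            g = gene_index.get(gene_id)
            if g is None:
                raise ValueError(f"gene {gene_id} not in universe")
            cur = best[s, g]
            take = np.isnan(cur) | (scores[i] > cur)
            best[s, g, take] = scores[i, take]
    columns = {}
    for m, pwm in enumerate(pwms):
        columns[pwm.motif_id] = rank_genes_from_species_scores(
            best[:, :, m], seed=_column_seed(seed, m))
    meta = {"seed": seed, "species": species_list,
            "crm_params": _params_dict(crm_params or CrmScoreParams())}
    return build_database(columns, universe, collection, meta)


def build_track_database(
    tracks: dict[str, pd.DataFrame],
    search_space: dict[str, list[Region]],
    universe: list[str],
    seed: int,
    collection: str = "tracks",
) -> RankingDatabase:
    """One ranking column per ChIP track from peak signalValues."""
    columns = {}
    for t, track_id in enumerate(sorted(tracks)):
        columns[track_id] = build_track_ranking(
            tracks[track_id], search_space, universe,
            seed=_column_seed(seed, t))
    return build_database(columns, universe, collection, {"seed": seed})


def _column_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2**31 - 1))


def _params_dict(p: CrmScoreParams) -> dict:
    return {"gap_expectation": p.gap_expectation, "pseudocount": p.pseudocount,
            "cluster_open_bits": p.cluster_open_bits,
            "background": None if p.background is None
            else list(map(float, p.background))}


# ---------------------------------------------------------------------------
# Validation experiments (planted signal, noise robustness)
# ---------------------------------------------------------------------------

def planted_study_config(seed: int = 0) -> SimulationConfig:
    """Study conditions of the planted-signal experiment: 1000 genes, 20
    targets, 1 true + 49 decoy PWMs, 3 species."""
    return SimulationConfig(seed=seed)


def noise_study_config(seed: int = 0) -> SimulationConfig:
    """Study conditions of the noise-robustness experiment: input sets of
    200 genes drawn from a 200-gene target pool in a 7000-gene universe, so
    the AUC top fraction (T = 210) is at least the set size, mirroring the
    geometry of top-200 target sets in a genome-scale universe."""
    return SimulationConfig(seed=seed, n_genes=7000, n_target_genes=200,
                            set_size=200)

@dataclass
class PlantedRunResult:
    """Outcome of one planted-signal run for the true motif."""

    true_rank: int           # 1-based NES rank of the true motif (0 = absent)
    true_nes: float
    n_reported: int
    sensitivity: float
    ppv: float
    selected_targets: list[str] = field(default_factory=list)
    results: list[EnrichmentResult] = field(default_factory=list)


def motif_nes_table(db: RankingDatabase, gene_set,
                    params: RecoveryParams | None = None) -> pd.DataFrame:
    """NES of every feature of one database for one gene set (no threshold)."""
    params = params or RecoveryParams()
    open_params = RecoveryParams(top_fraction=params.top_fraction,
                                 nes_threshold=-np.inf,
                                 rank_threshold=params.rank_threshold,
                                 nes_ddof=params.nes_ddof)
    results = run_enrichment(db, gene_set, open_params)
    return pd.DataFrame(
        [(r.feature_id, r.auc, r.nes) for r in results],
        columns=["feature_id", "AUC", "NES"])


def evaluate_planted_run(
    db: RankingDatabase,
    gene_set,
    true_targets,
    params: RecoveryParams | None = None,
    true_feature: str = TRUE_MOTIF_ID,
) -> PlantedRunResult:
    """Enrich one gene set and measure how the true feature fares.

    Sensitivity = selected true targets / all planted target genes (recall
    against the ground truth, so diluting the input necessarily lowers it);
    PPV = selected true targets / all selected.  Both are 0 when the true
    feature is not reported (or selects nothing).
    """
    params = params or RecoveryParams()
    results = run_enrichment(db, gene_set, params)
    truth = set(true_targets)
    true_rank, true_nes, sens, ppv = 0, 0.0, 0.0, 0.0
    selected: list[str] = []
    for i, res in enumerate(results, start=1):
        if res.feature_id == true_feature:
            true_rank, true_nes = i, res.nes
            selected = res.target_genes
            if selected:
                tp = len(set(selected) & truth)
                ppv = tp / len(selected)
                sens = tp / len(truth) if truth else 0.0
            break
    return PlantedRunResult(
        true_rank=true_rank, true_nes=true_nes, n_reported=len(results),
        sensitivity=sens, ppv=ppv, selected_targets=selected, results=results)


def planted_recovery_experiment(
    seeds,
    config: SimulationConfig | None = None,
    recovery_params: RecoveryParams | None = None,
    noise_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate + scan + enrich once per seed; one row per run."""
    rows = []
    for seed in seeds:
        base = config or SimulationConfig()
        cfg = SimulationConfig(**{**_config_dict(base), "seed": int(seed)})
        ds = simulate_dataset(cfg)
        db = build_motif_database(ds.sequences, ds.pwms, ds.universe,
                                  seed=cfg.seed)
        gene_set = ds.gene_sets[float(noise_fraction)]
        run = evaluate_planted_run(db, gene_set, ds.target_genes,
                                   recovery_params)
        rows.append((int(seed), run.true_rank, run.true_nes,
                     run.sensitivity, run.ppv, run.n_reported))
    return pd.DataFrame(rows, columns=[
        "seed", "true_rank", "true_nes", "sensitivity", "ppv", "n_reported"])


def noise_robustness_experiment(
    seeds,
    config: SimulationConfig | None = None,
    recovery_params: RecoveryParams | None = None,
) -> pd.DataFrame:
    """Re-enrich each simulated database at every configured noise fraction.

    The ranking database is built once per seed (it does not depend on the
    input set) and reused across fractions.
    """
    rows = []
    for seed in seeds:
        base = config or SimulationConfig()
        cfg = SimulationConfig(**{**_config_dict(base), "seed": int(seed)})
        ds = simulate_dataset(cfg)
        db = build_motif_database(ds.sequences, ds.pwms, ds.universe,
                                  seed=cfg.seed)
        for frac, gene_set in sorted(ds.gene_sets.items()):
            run = evaluate_planted_run(db, gene_set, ds.target_genes,
                                       recovery_params)
            rows.append((int(seed), frac, run.true_rank, run.true_nes,
                         run.sensitivity, run.ppv))
    return pd.DataFrame(rows, columns=[
        "seed", "noise_fraction", "true_rank", "true_nes",
        "sensitivity", "ppv"])


def _config_dict(config: SimulationConfig) -> dict:
    from dataclasses import asdict
    return asdict(config)
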