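"""Synthetic benchmark datasets for the whole pipeline.

The generator emulates the validation design of a planted-signal experiment:
a gene universe laid out on artificial chromosomes, one upstream regulatory
region per gene, multi-"species" orthologous sequences in which a subset of
target genes carries a planted homotypic cluster of a true motif, a PWM
collection of that motif plus decoys, ChIP-like peak tracks, and input gene
sets in which true targets are mixed with increasing fractions of noise
genes.  Orthology is simulated by per-base substitution of the same
coordinates (no indels), at a lower rate inside planted sites than outside
(conservation of functional sequence); cross-species region mapping is
therefore the identity.

Everything is deterministic given the seed, down to the bytes of the files
the dataset writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import PWM, BASES, write_clusterbuster
from .search_space import (GeneModel, Region, SearchSpaceMode,
                           delineate_search_space, write_annotation_table,
                           write_regions_bed)

TRUE_MOTIF_ID = "true_motif"
TRUE_TRACK_ID = "track_00_true"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    The defaults describe the planted-signal validation: a universe of 1000
    genes, 20 of which carry a homotypic cluster of one strong 12-bp motif
    (1 + Poisson(2) sites per region) hidden among 49 decoy PWMs, observed in
    3 species with 30% background / 5% in-site substitution per base.
    """

    seed: int = 0
    n_genes: int = 1000
    n_species: int = 3
    n_decoy_pwms: int = 49
    true_pwm_length: int = 12
    true_pwm_ic: float = 1.6          # bits per column
    n_target_genes: int = 20
    sites_per_region: float = 2.0     # lambda; a region gets 1 + Poisson(lambda)
    site_degradation_max: float = 0.25  # per-target site quality gradient
    background_substitution_rate: float = 0.30
    site_substitution_rate: float = 0.05
    gc_content: float = 0.42
    region_length: int = 500
    peak_noise_rate: float = 0.2      # background peaks per region per track
    n_tracks: int = 5
    noise_fractions: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    set_size: int | None = None       # defaults to n_target_genes

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_species", "n_decoy_pwms", "n_target_genes",
                     "true_pwm_length", "region_length", "n_tracks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_substitution_rate", "site_substitution_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.site_substitution_rate > self.background_substitution_rate:
            raise ValueError("site substitution rate must not exceed the "
                             "background rate (sites are conserved)")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_target_genes > self.n_genes:
            raise ValueError("more target genes than genes")
        # worst case plotted below uses the 99.9% Poisson quantile
        max_sites = 1 + int(np.ceil(
            self.sites_per_region + 4 * np.sqrt(self.sites_per_region) + 3))
        if self.region_length < max_sites * (self.true_pwm_length + 2):
            raise ValueError("region_length too short for the requested "
                             "number of planted sites")

    @property
    def effective_set_size(self) -> int:
        return self.set_size if self.set_size is not None else self.n_target_genes

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i}" for i in range(self.n_species)]


@dataclass
class PlantedSite:
    gene_id: str
    chrom: str
    genomic_start: int
    offset_in_region: int
    strand: str
    sequence: str


@dataclass
class SyntheticDataset:
    """All inputs of one simulated study, plus the ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    regions: dict[str, list[Region]]
    sequences: dict[str, dict[str, str]]  # species -> region_key -> sequence
    pwms: list[PWM]
    truth: pd.DataFrame                   # one row per planted site
    peaks: dict[str, pd.DataFrame]        # track_id -> BED-like frame
    gene_sets: dict[float, list[str]]     # noise fraction -> input set
    target_genes: list[str] = field(default_factory=list)

    @property
    def universe(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def true_pwm(self) -> PWM:
        return next(p for p in self.pwms if p.motif_id == TRUE_MOTIF_ID)

    def region_key(self, region: Region, index: int, species: str) -> str:
        return f"{region.gene_id}|{index}|{species}"

    def write(self, outdir: str | Path) -> None:
        """Write the dataset as plain-text files (FASTA/BED/TSV/GMT/JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation_table(self.genes, outdir / "annotation.tsv")
        write_regions_bed(self.regions, outdir / "regions.bed")
        for species, seqs in self.sequences.items():
            with open(outdir / f"sequences.{species}.fa", "w") as fh:
                for key in sorted(seqs):
                    fh.write(f">{key}\n{seqs[key]}\n")
        (outdir / "motifs.cb").write_text(write_clusterbuster(self.pwms))
        self.truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        for track_id, peaks in self.peaks.items():
            peaks.to_csv(outdir / f"peaks.{track_id}.bed", sep="\t",
                         index=False, header=False)
        with open(outdir / "gene_sets.gmt", "w") as fh:
            for frac in sorted(self.gene_sets):
                genes = self.gene_sets[frac]
                fh.write("\t".join([f"noise_{frac:g}", ".", *genes]) + "\n")
        (outdir / "config.json").write_text(
            json.dumps(asdict(self.config), sort_keys=True, indent=1) + "\n")


def _information_to_dominant_prob(ic: float) -> float:
    """Dominant-base probability of a (p, q, q, q) column with the given
    information content in bits (uniform background)."""
    from scipy.optimize import brentq

    def col_ic(p):
        q = (1.0 - p) / 3.0
        terms = p * np.log2(4 * p)
        if q > 0:
            terms += 3 * q * np.log2(4 * q)
        return terms - ic

    if ic >= 2.0 - 1e-9:
        return 1.0
    return float(brentq(col_ic, 0.2500001, 0.9999999))


def _make_true_pwm(config: SimulationConfig, rng: np.random.Generator) -> PWM:
    p_dom = _information_to_dominant_prob(config.true_pwm_ic)
    counts = np.empty((config.true_pwm_length, 4))
    dominants = rng.integers(0, 4, size=config.true_pwm_length)
    for j, d in enumerate(dominants):
        col = np.full(4, (1.0 - p_dom) / 3.0)
        col[d] = p_dom
        counts[j] = np.round(col * 100.0, 3)
    return PWM(TRUE_MOTIF_ID, counts, source_tag="synthetic")


def _make_decoys(config: SimulationConfig, true_pwm: PWM,
                 rng: np.random.Generator) -> list[PWM]:
    """Half column-shuffles of the true motif, half Dirichlet-random PWMs."""
    decoys = []
    n_shuf = config.n_decoy_pwms // 2
    for i in range(n_shuf):
        perm = rng.permutation(true_pwm.width)
        decoys.append(PWM(f"decoy_shuf_{i:03d}", true_pwm.counts[perm].copy(),
                          source_tag="synthetic"))
    for i in range(config.n_decoy_pwms - n_shuf):
        width = int(rng.integers(8, config.true_pwm_length + 3))
        alpha = float(rng.choice([0.2, 0.5, 1.0]))
        cols = rng.dirichlet(np.full(4, alpha), size=width)
        counts = np.round(np.clip(cols, 1e-4, None) * 100.0, 3)
        decoys.append(PWM(f"decoy_rand_{i:03d}", counts, source_tag="synthetic"))
    return decoys


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=probs)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _sample_site(pwm: PWM, rng: np.random.Generator) -> np.ndarray:
    probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    return np.array([rng.choice(4, p=probs[j]) for j in range(pwm.width)])


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic study, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)

    # -- gene annotation: genes laid out on chromosomes with margins wide
    # enough that each gene keeps a clean upstream window of region_length
    genes: list[GeneModel] = []
    genes_per_chrom = 50
    margin = config.region_length
    pos = margin + int(rng.integers(100, 1000))
    chrom_i = 0
    for i in range(config.n_genes):
        if i and i % genes_per_chrom == 0:
            chrom_i += 1
            pos = margin + int(rng.integers(100, 1000))
        chrom = f"chr{chrom_i + 1}"
        length = int(rng.integers(1000, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        tss = start if strand == "+" else end
        n_ex = int(rng.integers(1, 4))
        exons = []
        for _ in range(n_ex):
            ex_len = int(rng.integers(100, 300))
            ex_start = int(rng.integers(start + 50, end - ex_len - 1))
            exons.append((ex_start, ex_start + ex_len))
        genes.append(GeneModel(
            gene_id=f"g{i:04d}", chrom=chrom, strand=strand,
            span=(start, end), tss_list=[tss], coding_exons=sorted(exons)))
        pos = end + margin + int(rng.integers(200, 2000))

    universe = [g.gene_id for g in genes]

    # -- regions: the strand-aware upstream window of each TSS.  With the
    # default region_length of 500 this coincides with the up500 delineation
    # of the generated annotation (asserted in the test suite).
    if config.region_length == 500:
        regions = delineate_search_space(genes, SearchSpaceMode.up500)
    else:
        regions = {}
        for g in genes:
            tss = g.tss_list[0]
            if g.strand == "+":
                win = (tss - config.region_length, tss)
            else:
                win = (tss, tss + config.region_length)
            regions[g.gene_id] = [Region(g.chrom, max(0, win[0]), win[1],
                                         g.gene_id)]

    # -- PWM collection
    true_pwm = _make_true_pwm(config, rng)
    pwms = [true_pwm] + _make_decoys(config, true_pwm, rng)

    # -- target genes and planted sites in the base species
    target_idx = rng.choice(config.n_genes, size=config.n_target_genes,
                            replace=False)
    target_genes = sorted(universe[i] for i in target_idx)
    target_set = set(target_genes)

    base_species = config.species_ids[0]
    base_seqs: dict[str, np.ndarray] = {}
    site_mask: dict[str, np.ndarray] = {}
    truth_rows = []
    W = true_pwm.width
    for g in genes:
        for idx, region in enumerate(regions[g.gene_id]):
            key = f"{g.gene_id}|{idx}|{base_species}"
            L = region.length
            seq = _random_sequence(L, config.gc_content, rng)
            mask = np.zeros(L, dtype=bool)
            if g.gene_id in target_set and idx == 0:
                n_sites = 1 + int(rng.poisson(config.sites_per_region))
                # per-target site quality: strong and marginal targets both
                # exist, as in ChIP-derived positive sets
                degradation = float(rng.uniform(0.0, config.site_degradation_max))
                slot = L // n_sites
                if slot < W:
                    raise ValueError("region_length too short for planted sites")
                for s_i in range(n_sites):
                    jitter = int(rng.integers(0, slot - W + 1))
                    offset = s_i * slot + jitter
                    site = _sample_site(true_pwm, rng)
                    degrade = rng.random(W) < degradation
                    site[degrade] = (site[degrade]
                                     + rng.integers(1, 4, int(degrade.sum()))) % 4
                    strand = "+" if rng.random() < 0.5 else "-"
                    planted = site if strand == "+" else _revcomp_codes(site)
                    seq[offset:offset + W] = planted
                    mask[offset:offset + W] = True
                    truth_rows.append((
                        g.gene_id, region.chrom, region.start + offset,
                        offset, strand, _codes_to_str(planted)))
            base_seqs[key] = seq
            site_mask[key] = mask

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "chrom", "genomic_start", "offset_in_region", "strand",
        "site_sequence"])

    # -- orthologous species: per-base substitution, conserved inside sites
    sequences: dict[str, dict[str, str]] = {base_species: {
        key: _codes_to_str(seq) for key, seq in base_seqs.items()}}
    for species in config.species_ids[1:]:
        out: dict[str, str] = {}
        for key, seq in base_seqs.items():
            mask = site_mask[key]
            rate = np.where(mask, config.site_substitution_rate,
                            config.background_substitution_rate)
            mutate = rng.random(seq.size) < rate
            shifts = rng.integers(1, 4, size=int(mutate.sum()))
            mutated = seq.copy()
            mutated[mutate] = (mutated[mutate] + shifts) % 4
            out[key.rsplit("|", 1)[0] + f"|{species}"] = _codes_to_str(mutated)
        sequences[species] = out

    # -- peak tracks on base-species coordinates
    peaks: dict[str, pd.DataFrame] = {}
    all_regions = [(g.gene_id, idx, r)
                   for g in genes for idx, r in enumerate(regions[g.gene_id])]
    for t in range(config.n_tracks):
        track_id = TRUE_TRACK_ID if t == 0 else f"track_{t:02d}_noise"
        rows = []
        for gid, idx, region in all_regions:
            if t == 0 and gid in target_set and idx == 0:
                centre = region.start + region.length // 2
                half = int(rng.integers(100, max(101, region.length)))
                signal = float(rng.uniform(50.0, 150.0))
                rows.append((region.chrom, max(0, centre - half),
                             centre + half, f"{track_id}_{gid}", 0, ".",
                             round(signal, 3)))
            n_noise = int(rng.poisson(config.peak_noise_rate))
            for _ in range(n_noise):
                p_start = region.start + int(rng.integers(0, region.length))
                p_len = int(rng.integers(50, 400))
                signal = float(rng.uniform(1.0, 30.0))
                rows.append((region.chrom, p_start, p_start + p_len,
                             f"{track_id}_bg", 0, ".", round(signal, 3)))
        peaks[track_id] = pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "name", "score", "strand", "signalValue"])

    # -- input gene sets at the configured noise fractions
    gene_sets = {}
    for frac in config.noise_fractions:
        child_seed = int(rng.integers(0, 2**31 - 1))
        gene_sets[float(frac)] = mix_noise(
            target_genes, universe, frac, config.effective_set_size,
            seed=child_seed)

    return SyntheticDataset(
        config=config, genes=genes, regions=regions, sequences=sequences,
        pwms=pwms, truth=truth, peaks=peaks, gene_sets=gene_sets,
        target_genes=target_genes)


def mix_noise(
    true_targets,
    universe,
    noise_fraction: float,
    set_size: int,
    seed: int,
) -> list[str]:
    """An input set of exactly ``set_size`` genes with
    ``round(noise_fraction * set_size)`` non-targets (sampled without
    replacement from universe minus targets) replacing true targets."""
    if not (0.0 <= noise_fraction <= 1.0):
        raise ValueError("noise_fraction must be in [0, 1]")
    targets = sorted(set(true_targets))
    negatives = sorted(set(universe) - set(targets))
    n_noise = int(round(noise_fraction * set_size))
    n_true = set_size - n_noise
    if n_true > len(targets):
        raise ValueError(f"not enough true targets ({len(targets)}) for "
                         f"{n_true} positives")
    if n_noise > len(negatives):
        raise ValueError("not enough negative genes for the requested noise")
    rng = np.random.default_rng(seed)
    chosen = [str(g) for g in rng.choice(targets, size=n_true, replace=False)]
    chosen += [str(g) for g in rng.choice(negatives, size=n_noise, replace=False)]
    return sorted(chosen)
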