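"""Whole-universe gene rankings per feature, and their persistence.

Per species, regions are ranked by descending cluster score; a gene's
per-species rank ratio (best region's rank divided by the number of ranked
regions in that species) feeds an order-statistic aggregation that yields the
probability (q-value) of observing ranks at least that good across species by
chance.  Genes are ordered by ascending q-value; genes scoring zero in every
species are appended in seeded-random order, as are ties.

The order-statistic probability for sorted ratios r_(1) <= ... <= r_(K) is

    Q = K! * V_K,   V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} * r_(K-k+1)^i / i!

which is P(U_(1)<=r_(1), ..., U_(K)<=r_(K)) for K iid uniforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .search_space import Region

log = logging.getLogger(__name__)

RANKDB_FORMAT_VERSION = 1


def aggregate_species_ranks(ratios) -> float:
    """Order-statistic q-value for per-species rank ratios in (0, 1].

    Unsorted input is sorted internally.  The result is clamped to (0, 1].
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    if r.size == 0:
        raise ValueError("empty ratio list")
    if np.any(r <= 0.0) or np.any(r > 1.0):
        raise ValueError("ratios must lie in (0, 1]")
    K = r.size
    V = np.zeros(K + 1)
    V[0] = 1.0
    for k in range(1, K + 1):
        x = r[K - k]  # r_(K-k+1), 1-based order statistic
        term = 1.0
        acc = 0.0
        for i in range(1, k + 1):
            term *= x / i  # x**i / i!
            acc += (-1.0) ** (i - 1) * V[k - i] * term
        V[k] = acc
    q = math.factorial(K) * V[K]
    return float(min(1.0, max(q, 5e-324)))


def aggregate_species_ranks_many(ratios: np.ndarray) -> np.ndarray:
    """Vectorised q-values for a (K species x G genes) ratio matrix.

    NaN marks a missing species for a gene (dropped, reducing that gene's K).
    Genes with no ratios at all get q = 1.  Matches
    :func:`aggregate_species_ranks` gene by gene.
    """
    ratios = np.asarray(ratios, dtype=float)
    K_max, G = ratios.shape
    n_avail = np.sum(~np.isnan(ratios), axis=0)
    qvals = np.ones(G)
    # NaNs sort to the end, so the first k rows are the sorted ratios
    sorted_r = np.sort(ratios, axis=0)
    for k in range(1, K_max + 1):
        cols = np.where(n_avail == k)[0]
        if cols.size == 0:
            continue
        r = sorted_r[:k, cols]  # (k, n) ascending
        V = np.zeros((k + 1, cols.size))
        V[0] = 1.0
        for kk in range(1, k + 1):
            x = r[k - kk]
            term = np.ones(cols.size)
            acc = np.zeros(cols.size)
            for i in range(1, kk + 1):
                term = term * x / i
                acc += (-1.0) ** (i - 1) * V[kk - i] * term
            V[kk] = acc
        q = math.factorial(k) * V[k]
        qvals[cols] = np.clip(q, 5e-324, 1.0)
    return qvals


# ---------------------------------------------------------------------------
# Ranking database
# ---------------------------------------------------------------------------

def universe_hash(universe: list[str]) -> str:
    h = hashlib.sha256()
    for g in universe:
        h.update(g.encode())
        h.update(b"\n")
    return h.hexdigest()


@dataclass
class RankingDatabase:
    """Per-feature total orderings of a gene universe.

    ``ranks[g, f]`` is the 1-based rank of gene ``universe[g]`` under feature
    ``features[f]``; every column is a permutation of 1..G.
    """

    universe: list[str]
    features: list[str]
    collection: str
    ranks: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int32)
        G, N = len(self.universe), len(self.features)
        if self.ranks.shape != (G, N):
            raise ValueError(f"rank matrix shape {self.ranks.shape} != ({G},{N})")
        expected = np.arange(1, G + 1)
        for f in range(N):
            if not np.array_equal(np.sort(self.ranks[:, f]), expected):
                raise ValueError(
                    f"column {self.features[f]} is not a permutation of 1..{G}")
        self._gene_index = {g: i for i, g in enumerate(self.universe)}

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def gene_indices(self, genes) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=np.int64)

    def column(self, feature_id: str) -> np.ndarray:
        return self.ranks[:, self.features.index(feature_id)]

    @property
    def universe_sha256(self) -> str:
        return universe_hash(self.universe)

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.rankdb`` (binary rank matrix) and
        ``<prefix>.meta.json`` (universe, features, parameters)."""
        prefix = Path(prefix)
        rank_path = prefix.with_suffix(".rankdb")
        meta_path = prefix.with_suffix(".meta.json")
        with open(rank_path, "wb") as fh:
            np.save(fh, self.ranks)
        meta = {
            "format_version": RANKDB_FORMAT_VERSION,
            "collection": self.collection,
            "universe": self.universe,
            "features": self.features,
            "universe_sha256": self.universe_sha256,
            "metadata": self.metadata,
        }
        meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
        return rank_path, meta_path

    @classmethod
    def load(cls, prefix: str | Path) -> "RankingDatabase":
        prefix = Path(prefix)
        if prefix.suffix in {".rankdb", ".json"}:
            prefix = prefix.with_suffix("") if prefix.suffix == ".rankdb" \
                else Path(str(prefix)[: -len(".meta.json")])
        with open(prefix.with_suffix(".rankdb"), "rb") as fh:
            ranks = np.load(fh)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        return cls(universe=meta["universe"], features=meta["features"],
                   collection=meta["collection"], ranks=ranks,
                   metadata=meta.get("metadata", {}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=self.universe, columns=self.features)

    def export_tsv(self, path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def _ranks_from_order(order: np.ndarray) -> np.ndarray:
    """Invert an ordering (best-first indices) into 1-based ranks."""
    ranks = np.empty(order.size, dtype=np.int32)
    ranks[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return ranks


def _seeded_order(keys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """argsort ascending by ``keys`` with seeded random tie-breaking."""
    tie = rng.random(keys.size)
    return np.lexsort((tie, keys))


# ---------------------------------------------------------------------------
# Motif rankings
# ---------------------------------------------------------------------------

def rank_genes_from_species_scores(
    gene_scores: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Turn a (K species x G genes) best-region score matrix into ranks.

    NaN marks a gene absent from a species (that species is dropped from the
    gene's order-statistic, K reduced).  Genes with score 0 (or absent) in
    every species are appended at the end in seeded-random order.
    """
    scores = np.asarray(gene_scores, dtype=float)
    K, G = scores.shape
    rng = np.random.default_rng(seed)
    ratios = np.full((K, G), np.nan)
    for s in range(K):
        present = ~np.isnan(scores[s])
        n_s = int(present.sum())
        if n_s == 0:
            continue
        order = _seeded_order(-scores[s, present], rng)
        r = _ranks_from_order(order)
        ratios[s, present] = r / n_s
    qvals = aggregate_species_ranks_many(ratios)
    all_zero = np.all(np.isnan(scores) | (scores == 0.0), axis=0)
    key = qvals.copy()
    key[all_zero] = 2.0  # beyond any q-value: forced to the tail
    order = _seeded_order(key, rng)
    return _ranks_from_order(order)


def build_motif_ranking(
    scores: pd.DataFrame,
    universe: list[str],
    seed: int,
) -> np.ndarray:
    """One ranking column for one motif from its per-region scores.

    ``scores`` has columns gene_id, species_id, score (one row per region;
    extra columns ignored).  Per species, regions are ranked by descending
    score and each gene keeps its best region's rank ratio.
    """
    unknown = set(scores["gene_id"]) - set(universe)
    if unknown:
        raise ValueError(f"genes not in universe: {sorted(unknown)[:5]}")
    gene_idx = {g: i for i, g in enumerate(universe)}
    species = sorted(scores["species_id"].unique())
    G = len(universe)
    rng = np.random.default_rng(seed)
    ratios = np.full((len(species), G), np.nan)
    zero_mask = np.ones((len(species), G), dtype=bool)
    for s, sp in enumerate(species):
        sub = scores[scores["species_id"] == sp]
        vals = sub["score"].to_numpy(dtype=float)
        gidx = np.array([gene_idx[g] for g in sub["gene_id"]], dtype=np.int64)
        order = _seeded_order(-vals, rng)
        region_rank = _ranks_from_order(order).astype(float)
        n_regions = vals.size
        best = np.full(G, np.inf)
        np.minimum.at(best, gidx, region_rank)
        present = np.isfinite(best)
        ratios[s, present] = best[present] / n_regions
        nz = np.zeros(G, dtype=bool)
        np.logical_or.at(nz, gidx, vals > 0)
        zero_mask[s] = ~nz
    qvals = aggregate_species_ranks_many(ratios)
    all_zero = np.all(np.isnan(ratios) | zero_mask, axis=0)
    key = qvals.copy()
    key[all_zero] = 2.0
    order = _seeded_order(key, rng)
    return _ranks_from_order(order)


# ---------------------------------------------------------------------------
# Track rankings
# ---------------------------------------------------------------------------

def read_peak_bed(path_or_buf) -> pd.DataFrame:
    """Read BED/narrowPeak peaks; the signal is column 7 (signalValue) when
    present, else column 5 (score).  Malformed lines are skipped with a
    logged count."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    rows = []
    skipped = 0
    for line in lines:
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError
            signal = float(f[6]) if len(f) >= 7 else float(f[4])
        except (IndexError, ValueError):
            skipped += 1
            continue
        rows.append((chrom, start, end, signal))
    if skipped:
        log.warning("skipped %d malformed BED lines", skipped)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "signalValue"])
    df.attrs["n_skipped"] = skipped
    return df


def gene_peak_scores(
    peaks: pd.DataFrame,
    search_space: dict[str, list[Region]],
) -> dict[str, float]:
    """Max signalValue over all peaks overlapping (>= 1 bp) any gene region."""
    trees: dict[str, IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.signalValue)
    out: dict[str, float] = {}
    for gid, regions in search_space.items():
        best = 0.0
        for reg in regions:
            tree = trees.get(reg.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(reg.start, reg.end):
                if hit.data > best:
                    best = hit.data
        out[gid] = best
    return out


def build_track_ranking(
    peaks: pd.DataFrame,
    search_space: dict[str, list[Region]],
    universe: list[str],
    seed: int,
) -> np.ndarray:
    """One ranking column for one ChIP track: genes by descending maximum
    signalValue over their regions; zero-overlap genes in seeded-random order
    at the end."""
    unknown = set(search_space) - set(universe)
    if unknown:
        raise ValueError(f"genes not in universe: {sorted(unknown)[:5]}")
    scores_map = gene_peak_scores(peaks, search_space)
    scores = np.array([scores_map.get(g, 0.0) for g in universe])
    rng = np.random.default_rng(seed)
    key = -scores
    key[scores == 0.0] = np.inf  # zero-overlap genes forced to the tail
    order = _seeded_order(key, rng)
    return _ranks_from_order(order)


def build_database(
    columns: dict[str, np.ndarray],
    universe: list[str],
    collection: str,
    metadata: dict | None = None,
) -> RankingDatabase:
    """Assemble named ranking columns into a :class:`RankingDatabase`."""
    features = list(columns)
    ranks = np.stack([columns[f] for f in features], axis=1) if features else \
        np.zeros((len(universe), 0), dtype=np.int32)
    return RankingDatabase(universe=list(universe), features=features,
                           collection=collection, ranks=ranks,
                           metadata=metadata or {})
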