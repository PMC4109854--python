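"""Recovery-curve enrichment of a gene set against ranking databases.

For each feature the cumulative recovery curve c(k) counts how many input
genes sit at rank <= k.  Enrichment is the area under that curve restricted
to the top fraction of the ranking (AUC), z-scored across the feature
collection into a normalized enrichment score (NES).  The candidate direct
targets of an enriched feature are the input genes ranked above the leading
edge: the rank where the feature's recovery maximally exceeds the collection
background (mean recovery + 2 SD across all features of the collection).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import RankingDatabase

log = logging.getLogger(__name__)


@dataclass
class RecoveryParams:
    """Enrichment parameters.

    top_fraction: fraction of the ranking over which the AUC is computed.
    nes_threshold: minimum NES for a feature to be reported.
    rank_threshold: maximum rank considered for the leading-edge search.
    nes_ddof: 1 for the sample standard deviation in NES (default), 0 for
        the population form.
    """

    top_fraction: float = 0.03
    nes_threshold: float = 3.0
    rank_threshold: int = 5000
    nes_ddof: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.rank_threshold < 1:
            raise ValueError("rank_threshold must be >= 1")

    def top_rank(self, n_genes: int) -> int:
        return max(1, math.ceil(self.top_fraction * n_genes))


@dataclass
class RecoveryCurve:
    """Cumulative recovery c(k) of a gene set along one feature's ranking."""

    feature_id: str
    counts: np.ndarray  # c(k) for k = 1..depth
    set_size: int
    n_genes: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.set_size


@dataclass
class EnrichmentResult:
    """One enriched feature with its targets above the leading edge."""

    feature_id: str
    collection: str
    auc: float
    nes: float
    leading_edge_rank: int
    candidate_targets: list[tuple[str, int]] = field(default_factory=list)

    @property
    def target_genes(self) -> list[str]:
        return [g for g, _ in self.candidate_targets]


def _effective_set(universe_index: dict[str, int], gene_set) -> list[str]:
    genes, dropped = [], []
    seen = set()
    for g in gene_set:
        if g in seen:
            continue
        seen.add(g)
        (genes if g in universe_index else dropped).append(g)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) not in the ranking universe "
                      f"were dropped (e.g. {dropped[:3]})", stacklevel=3)
    if not genes:
        raise ValueError("no usable genes: input set does not intersect universe")
    return genes


def recovery_curve(
    ranks: np.ndarray,
    depth: int,
    set_size: int | None = None,
    feature_id: str = "",
    n_genes: int = 0,
) -> RecoveryCurve:
    """c(k), k=1..depth, from the ranks of the set members under one feature."""
    set_size = set_size or ranks.size
    hits = np.bincount(ranks[ranks <= depth], minlength=depth + 1)[1:]
    return RecoveryCurve(feature_id, np.cumsum(hits), set_size, n_genes)


def compute_recovery_auc(
    ranking_column: np.ndarray,
    universe: list[str],
    gene_set,
    params: RecoveryParams | None = None,
) -> float:
    """AUC of the recovery curve in the top fraction of one ranking column.

    AUC = sum_{k=1..T} c(k) / (T * s) with T = ceil(top_fraction * G).
    """
    params = params or RecoveryParams()
    index = {g: i for i, g in enumerate(universe)}
    genes = _effective_set(index, gene_set)
    ranks = np.array([ranking_column[index[g]] for g in genes])
    T = params.top_rank(len(universe))
    return _auc_from_ranks(ranks, T, len(genes))


def _auc_from_ranks(ranks: np.ndarray, T: int, s: int) -> float:
    # sum_{k=1..T} c(k) = sum over members with rank rho <= T of (T - rho + 1)
    contrib = T - ranks + 1
    return float(contrib[contrib > 0].sum() / (T * s))


def normalize_nes(aucs, ddof: int = 1) -> np.ndarray:
    """z-score AUCs within one collection (sample SD by default).

    A degenerate collection (zero SD) yields all-zero NES with a warning.
    """
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 3:
        raise ValueError("NES normalization needs >= 3 features per collection")
    sd = aucs.std(ddof=ddof)
    if sd == 0.0 or np.all(aucs == aucs[0]):
        warnings.warn("degenerate collection: all AUCs equal, NES set to 0",
                      stacklevel=2)
        return np.zeros_like(aucs)
    return (aucs - aucs.mean()) / sd


def collection_background(curves: list[RecoveryCurve]) -> np.ndarray:
    """Background envelope b(k): mean recovery fraction across features plus
    two population standard deviations, at each rank k."""
    if len(curves) < 3:
        raise ValueError("background needs >= 3 features in the collection")
    fracs = np.stack([c.fractions for c in curves])
    return fracs.mean(axis=0) + 2.0 * fracs.std(axis=0, ddof=0)


def select_targets_leading_edge(
    curve: RecoveryCurve,
    background: np.ndarray,
    member_ranks: dict[str, int],
    rank_threshold: int,
) -> tuple[int, list[tuple[str, int]]]:
    """Leading-edge rank k* and the input genes ranked above it.

    k* is the smallest rank (<= rank_threshold) maximising signal minus
    background; if that maximum is <= 0, no targets are returned (k* = 0).
    """
    depth = min(rank_threshold, curve.counts.size, background.size)
    diff = curve.fractions[:depth] - background[:depth]
    k_star = int(np.argmax(diff)) + 1
    if diff[k_star - 1] <= 0.0:
        return 0, []
    targets = sorted(((g, r) for g, r in member_ranks.items() if r <= k_star),
                     key=lambda t: t[1])
    return k_star, targets


def run_enrichment(
    databases: RankingDatabase | list[RankingDatabase],
    gene_set,
    params: RecoveryParams | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment of one gene set against one or more collections.

    Each database is one collection; AUC distributions are kept separate per
    collection for NES normalization.  Features with NES >= the threshold are
    reported, sorted by NES descending, with their leading-edge targets.
    """
    params = params or RecoveryParams()
    if isinstance(databases, RankingDatabase):
        databases = [databases]
    results: list[EnrichmentResult] = []
    for db in databases:
        index = {g: i for i, g in enumerate(db.universe)}
        genes = _effective_set(index, gene_set)
        s = len(genes)
        G = db.n_genes
        T = params.top_rank(G)
        depth = min(params.rank_threshold, G)
        idx = db.gene_indices(genes)
        rank_matrix = db.ranks[idx, :]  # (s, N)
        aucs = np.array([
            _auc_from_ranks(rank_matrix[:, f], T, s)
            for f in range(len(db.features))
        ])
        nes = normalize_nes(aucs, ddof=params.nes_ddof)
        curves = [
            recovery_curve(rank_matrix[:, f], depth, s, db.features[f], G)
            for f in range(len(db.features))
        ]
        background = collection_background(curves)
        order = np.argsort(-nes, kind="stable")
        for f in order:
            if nes[f] < params.nes_threshold:
                break
            member_ranks = {g: int(rank_matrix[i, f]) for i, g in enumerate(genes)}
            k_star, targets = select_targets_leading_edge(
                curves[f], background, member_ranks, depth)
            results.append(EnrichmentResult(
                feature_id=db.features[f], collection=db.collection,
                auc=float(aucs[f]), nes=float(nes[f]),
                leading_edge_rank=k_star, candidate_targets=targets))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.collection, r.feature_id, r.auc, r.nes, r.leading_edge_rank,
         len(r.candidate_targets), ",".join(r.target_genes))
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "collection", "feature_id", "AUC", "NES", "leading_edge_rank",
        "n_targets", "targets"])


def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")
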