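"""Mapping enriched motifs to candidate transcription factors.

The association graph is heterogeneous: motif-TF *annotation* edges (a motif
curated for a TF, possibly of another species), TF-TF *homology* edges (with
a percent-identity), and motif-motif *similarity* edges (with a p-value).
Candidates for a motif are TFs reachable by a path containing exactly one
annotation edge, at most one similarity edge (taken before the annotation)
and at most one homology edge (taken after it) — chaining two indirect edges
of the same type is not allowed.

Candidates are ranked by tier: directly annotated TFs first, then TFs whose
gene is in the input set, then TFs found via homology, then TFs found via
motif similarity; within a tier the shortest path wins, then higher identity,
then lower similarity p-value, then the TF name.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .pwm import PWM, MIN_SCORING_WIDTH

TIERS = ("direct", "in_input_set", "homology", "similarity")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}

#: Minimum overlapping columns for a motif-motif alignment.
MIN_ALIGN_OVERLAP = 5


@dataclass
class Motif2TFParams:
    """Edge filters applied before traversal, and the species whose TFs are
    acceptable candidates (TFs annotated for another species can be crossed
    via homology but are not themselves returned)."""

    min_identity_pct: float = 0.0
    max_similarity_p: float = 0.001
    target_species: str = "human"


@dataclass
class TFCandidate:
    """A candidate TF for a query motif, with the path that supports it."""

    tf_id: str
    tier: str
    path: list[tuple[str, str, str]]  # (node_a, edge_type, node_b)
    identity_pct: float | None = None
    similarity_p: float | None = None
    rank: int = 0

    @property
    def path_length(self) -> int:
        return len(self.path)


class Motif2TFGraph:
    """Undirected typed graph over motif and TF nodes."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_annotation(self, motif_id: str, tf_id: str, species: str = "human") -> None:
        self.graph.add_node(motif_id, kind="motif")
        self.graph.add_node(tf_id, kind="tf", species=species)
        self.graph.add_edge(motif_id, tf_id, type="annotation")

    def add_homology(self, tf_a: str, tf_b: str, identity_pct: float) -> None:
        if not (0.0 <= identity_pct <= 100.0):
            raise ValueError("identity_pct must be in [0, 100]")
        for tf in (tf_a, tf_b):
            if tf not in self.graph:
                self.graph.add_node(tf, kind="tf", species="")
        self.graph.add_edge(tf_a, tf_b, type="homology", identity_pct=identity_pct)

    def add_similarity(self, motif_a: str, motif_b: str, p_value: float) -> None:
        if not (0.0 < p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        for m in (motif_a, motif_b):
            self.graph.add_node(m, kind="motif")
        self.graph.add_edge(motif_a, motif_b, type="similarity", p_value=p_value)

    def _neighbors(self, node: str, edge_type: str):
        for nbr, attrs in self.graph.adj[node].items():
            if attrs["type"] == edge_type:
                yield nbr, attrs

    @classmethod
    def from_tables(
        cls,
        annotations: pd.DataFrame,
        homology: pd.DataFrame | None = None,
        similarity: pd.DataFrame | None = None,
    ) -> "Motif2TFGraph":
        """Build from the three TSV tables: annotations (motif_id, tf_id,
        species), homology (tf_a, tf_b, identity_pct), similarity (motif_a,
        motif_b, p_value)."""
        g = cls()
        for row in annotations.itertuples(index=False):
            g.add_annotation(row.motif_id, row.tf_id,
                             getattr(row, "species", "human"))
        if homology is not None:
            for row in homology.itertuples(index=False):
                g.add_homology(row.tf_a, row.tf_b, float(row.identity_pct))
        if similarity is not None:
            for row in similarity.itertuples(index=False):
                g.add_similarity(row.motif_a, row.motif_b, float(row.p_value))
        return g


def map_motif_to_tfs(
    motif_id: str,
    graph: Motif2TFGraph,
    input_genes=(),
    params: Motif2TFParams | None = None,
) -> list[TFCandidate]:
    """All candidate TFs for a motif, ranked by tier and path quality.

    A motif absent from the graph yields an empty list.
    """
    params = params or Motif2TFParams()
    input_genes = set(input_genes)
    g = graph.graph
    if motif_id not in g:
        return []

    # enumerate paths: [similarity]? -> annotation -> [homology]?
    candidates: dict[str, TFCandidate] = {}

    def consider(tf_id, path, identity, sim_p):
        species = g.nodes[tf_id].get("species")
        if species not in (None, "", params.target_species):
            return
        used_sim = sim_p is not None
        used_hom = identity is not None
        if not used_sim and not used_hom:
            tier = "direct"
        elif tf_id in input_genes:
            tier = "in_input_set"
        elif not used_sim:
            tier = "homology"
        else:
            tier = "similarity"
        cand = TFCandidate(tf_id=tf_id, tier=tier, path=path,
                           identity_pct=identity, similarity_p=sim_p)
        prev = candidates.get(tf_id)
        if prev is None or _sort_key(cand) < _sort_key(prev):
            candidates[tf_id] = cand

    sim_steps: list[tuple[str, float | None, list]] = [(motif_id, None, [])]
    for nbr, attrs in graph._neighbors(motif_id, "similarity"):
        p = attrs["p_value"]
        if p <= params.max_similarity_p:
            sim_steps.append((nbr, p, [(motif_id, "similarity", nbr)]))
    for motif, sim_p, sim_path in sim_steps:
        for tf, _ in graph._neighbors(motif, "annotation"):
            ann_path = sim_path + [(motif, "annotation", tf)]
            consider(tf, ann_path, None, sim_p)
            for tf2, hattrs in graph._neighbors(tf, "homology"):
                ident = hattrs["identity_pct"]
                if ident >= params.min_identity_pct:
                    consider(tf2, ann_path + [(tf, "homology", tf2)],
                             ident, sim_p)

    ranked = sorted(candidates.values(), key=_sort_key)
    for i, cand in enumerate(ranked, start=1):
        cand.rank = i
    return ranked


def _sort_key(c: TFCandidate):
    identity = 100.0 if c.identity_pct is None else c.identity_pct
    sim_p = 0.0 if c.similarity_p is None else c.similarity_p
    return (_TIER_ORDER[c.tier], c.path_length, -identity, sim_p, c.tf_id)


def candidates_to_frame(candidates: list[TFCandidate]) -> pd.DataFrame:
    rows = [
        (c.rank, c.tf_id, c.tier, c.path_length,
         "" if c.identity_pct is None else c.identity_pct,
         "" if c.similarity_p is None else c.similarity_p,
         ";".join(f"{a}-{t}-{b}" for a, t, b in c.path))
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=[
        "rank", "tf_id", "tier", "path_length", "identity_pct",
        "similarity_p", "path"])


# ---------------------------------------------------------------------------
# Native motif similarity (a stand-in for an external alignment p-value;
# precomputed similarity tables are the recommended production input)
# ---------------------------------------------------------------------------

def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability columns; 0 when degenerate."""
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((da * da).sum()), np.sqrt((db * db).sum())
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((da * db).sum() / (na * nb))


def _best_alignment_score(pa: np.ndarray, pb: np.ndarray,
                          min_overlap: int) -> float | None:
    """Max over ungapped offsets of the mean per-column correlation."""
    wa, wb = pa.shape[0], pb.shape[0]
    best = None
    for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a = max(0, offset)
        hi_a = min(wa, offset + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols_a = pa[lo_a:hi_a]
        cols_b = pb[lo_a - offset:hi_a - offset]
        score = np.mean([
            _column_correlation(cols_a[i], cols_b[i])
            for i in range(cols_a.shape[0])
        ])
        if best is None or score > best:
            best = float(score)
    return best


def motif_similarity(
    pwm_a: PWM,
    pwm_b: PWM,
    n_shuffles: int = 999,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Similarity score and empirical p-value between two PWMs.

    Score: max over all ungapped offsets and both orientations (>= 5
    overlapping columns) of the mean per-column Pearson correlation of
    pseudocounted probability columns.  p-value: rank of the observed score
    among column-shuffled copies of ``pwm_b``:
    p = (1 + #{shuffled >= observed}) / (1 + n_shuffles).

    Returns ``None`` when the overlap constraint cannot be met (no edge).
    """
    if pwm_a.width < MIN_SCORING_WIDTH or pwm_b.width < MIN_SCORING_WIDTH:
        raise ValueError("PWMs must have length >= 4")
    min_overlap = MIN_ALIGN_OVERLAP
    if min(pwm_a.width, pwm_b.width) < min_overlap:
        return None

    pa = pwm_a.probabilities()

    def score_against(pb_counts: np.ndarray) -> float | None:
        pwm = PWM("tmp", pb_counts)
        scores = []
        for orient in (pwm, pwm.reverse_complement()):
            s = _best_alignment_score(pa, orient.probabilities(), min_overlap)
            if s is not None:
                scores.append(s)
        return max(scores) if scores else None

    observed = score_against(pwm_b.counts)
    if observed is None:
        return None
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pwm_b.width)
        s = score_against(pwm_b.counts[perm])
        if s is not None and s >= observed - 1e-12:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_shuffles)
    return observed, float(p_value)


def similarity_table(
    pwms: list[PWM],
    n_shuffles: int = 199,
    seed: int = 0,
    max_p: float = 1.0,
) -> pd.DataFrame:
    """All-vs-all similarity edges (motif_a, motif_b, score, p_value)."""
    rows = []
    for i, a in enumerate(pwms):
        for b in pwms[i + 1:]:
            res = motif_similarity(a, b, n_shuffles=n_shuffles, seed=seed)
            if res is None:
                continue
            score, p = res
            if p <= max_p:
                rows.append((a.motif_id, b.motif_id, score, p))
    return pd.DataFrame(rows, columns=["motif_a", "motif_b", "score", "p_value"])
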