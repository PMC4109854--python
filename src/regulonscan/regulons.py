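"""Regulon assembly, meta-regulon aggregation, and the leading-edge
hypergeometric enrichment test used for external validation.

A regulon is a TF together with the union of the candidate-target sets of
every enriched feature (motif or track) mapped to that TF; each target
carries the number of supporting features.  Enriched features that map to no
TF are kept as orphan entries.  Applying the pipeline to a batch of gene
sets yields a meta-regulon per TF: each target annotated with the number of
gene sets in which the TF was enriched and the gene fell in its optimal
target subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .motif2tf import TFCandidate
from .recovery import EnrichmentResult


@dataclass
class Regulon:
    """A TF (or orphan feature) with its merged direct-target set."""

    tf_id: str | None
    targets: dict[str, int]  # gene -> number of supporting features
    features: list[tuple[str, str, float]]  # (feature_id, collection, NES)
    best_nes: float

    @property
    def is_orphan(self) -> bool:
        return self.tf_id is None

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class MetaRegulon:
    """Per-TF target recurrence over a batch of analyzed gene sets."""

    tf_id: str
    recurrence: dict[str, int]
    n_gene_sets: int = 0


def assemble_regulons(
    results: list[EnrichmentResult],
    tf_candidates: dict[str, list[TFCandidate]],
) -> list[Regulon]:
    """Merge enriched features into per-TF regulons.

    Every candidate TF of a feature receives that feature's target set; a
    feature without candidates becomes an orphan regulon (tf_id ``None``).
    Regulons are sorted by best NES descending (orphans interleaved by the
    same key; ties by TF name).
    """
    per_tf: dict[str | None, dict] = {}
    orphans: list[Regulon] = []
    for res in results:
        cands = tf_candidates.get(res.feature_id, [])
        feature = (res.feature_id, res.collection, res.nes)
        if not cands:
            orphans.append(Regulon(
                tf_id=None,
                targets={g: 1 for g in res.target_genes},
                features=[feature], best_nes=res.nes))
            continue
        for cand in cands:
            rec = per_tf.setdefault(cand.tf_id, {"targets": {}, "features": []})
            rec["features"].append(feature)
            for g in res.target_genes:
                rec["targets"][g] = rec["targets"].get(g, 0) + 1
    regulons = [
        Regulon(tf_id=tf, targets=rec["targets"], features=rec["features"],
                best_nes=max(n for _, _, n in rec["features"]))
        for tf, rec in per_tf.items()
    ]
    regulons.extend(orphans)
    regulons.sort(key=lambda r: (-r.best_nes, r.tf_id or "~"))
    return regulons


def aggregate_meta_regulon(
    batch: list[list[Regulon]],
    tf_id: str,
    min_count: int = 1,
) -> MetaRegulon:
    """Recurrence of each target gene of one TF across a batch of runs.

    A gene counts once per gene set in which the TF has a regulon containing
    it; targets with recurrence below ``min_count`` are dropped.
    """
    counts: dict[str, int] = {}
    for run in batch:
        genes_this_run: set[str] = set()
        for reg in run:
            if reg.tf_id == tf_id:
                genes_this_run.update(reg.targets)
        for g in genes_this_run:
            counts[g] = counts.get(g, 0) + 1
    kept = {g: c for g, c in counts.items() if c >= min_count}
    return MetaRegulon(tf_id=tf_id, recurrence=kept, n_gene_sets=len(batch))


def rank_set_enrichment_test(
    ranking: dict[str, int],
    gene_set,
) -> tuple[int, int, float]:
    """GSEA-style leading edge with a hypergeometric tail p-value.

    ``ranking`` maps every universe gene to its 1-based rank (a permutation).
    The running difference d(k) = c(k)/s - k/G peaks at the leading edge k*
    (smallest argmax); x = c(k*) set members are recovered there, and the
    p-value is P[X >= x] for X ~ Hypergeom(G, s, k*).
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    G = len(ranking)
    ranks = sorted(ranking[g] for g in genes if g in ranking)
    if not ranks:
        raise ValueError("gene set does not intersect the ranked universe")
    s = len(ranks)
    hits = np.bincount(np.array(ranks), minlength=G + 1)[1:]
    c = np.cumsum(hits)
    k = np.arange(1, G + 1)
    d = c / s - k / G
    k_star = int(np.argmax(d)) + 1
    x = int(c[k_star - 1])
    p = float(hypergeom.sf(x - 1, G, s, k_star))
    return k_star, x, p


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gmt(path_or_buf) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    sets: dict[str, list[str]] = {}
    for line in lines:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def regulons_to_frame(regulons: list[Regulon]) -> pd.DataFrame:
    rows = []
    for r in regulons:
        targets = sorted(r.targets.items(), key=lambda t: (-t[1], t[0]))
        rows.append((
            r.tf_id or "", r.best_nes, r.n_features,
            ";".join(f"{fid}({coll})" for fid, coll, _ in r.features),
            len(r.targets),
            ",".join(f"{g}:{c}" for g, c in targets),
        ))
    return pd.DataFrame(rows, columns=[
        "tf_id", "best_NES", "n_features", "features", "n_targets", "targets"])


def regulons_to_sif(regulons: list[Regulon]) -> str:
    """Simple SIF edge list: ``tf regulates target`` per line."""
    lines = []
    for r in regulons:
        if r.is_orphan:
            continue
        for g in sorted(r.targets):
            lines.append(f"{r.tf_id}\tregulates\t{g}")
    return "\n".join(lines) + ("\n" if lines else "")
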