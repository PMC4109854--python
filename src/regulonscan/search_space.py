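"""Delineation of the regulatory search space around genes.

Each gene gets one candidate window per transcript TSS (500 bp upstream, or
5/10 kb on both sides of the TSS).  Windows of the same gene are merged,
truncated at the span of any neighbouring gene, and coding exons of *all*
genes are subtracted — a window may therefore split into several regions, or
vanish entirely.  All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

log = logging.getLogger(__name__)

#: Fragments shorter than this after subtraction are dropped.
MIN_REGION_LENGTH = 10

Interval = tuple[int, int]


class SearchSpaceMode(str, Enum):
    """Window geometry around each TSS.

    ``up500``   [TSS-500, TSS) on the gene's strand (strand-aware upstream).
    ``tss10kb`` [TSS-5kb, TSS+5kb).
    ``tss20kb`` [TSS-10kb, TSS+10kb).
    """

    up500 = "up500"
    tss10kb = "tss10kb"
    tss20kb = "tss20kb"

    def window(self, tss: int, strand: str) -> Interval:
        if self is SearchSpaceMode.up500:
            if strand == "+":
                return (tss - 500, tss)
            return (tss, tss + 500)
        half = 5000 if self is SearchSpaceMode.tss10kb else 10000
        return (tss - half, tss + half)

    @property
    def window_length(self) -> int:
        return 500 if self is SearchSpaceMode.up500 else (
            10000 if self is SearchSpaceMode.tss10kb else 20000)


@dataclass
class GeneModel:
    """A gene with its transcript TSSs, span and coding exons."""

    gene_id: str
    chrom: str
    strand: str
    span: Interval
    tss_list: list[int]
    coding_exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.tss_list:
            raise ValueError(f"{self.gene_id}: tss_list must be non-empty")
        if self.span[0] >= self.span[1]:
            raise ValueError(f"{self.gene_id}: empty span")
        for s, e in self.coding_exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty coding exon ({s},{e})")


@dataclass(frozen=True)
class Region:
    """A regulatory region assigned to a gene (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty region [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Interval arithmetic (sorted, half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals; touching intervals are merged."""
    if not intervals:
        return []
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: list[Interval], cut: list[Interval]) -> list[Interval]:
    """Remove the union of ``cut`` from each interval in ``base``."""
    cut = merge_intervals(cut)
    out: list[Interval] = []
    for s, e in base:
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------

def delineate_search_space(
    genes: list[GeneModel],
    mode: SearchSpaceMode | str,
    min_region_length: int = MIN_REGION_LENGTH,
) -> dict[str, list[Region]]:
    """Compute the per-gene regulatory regions for a search-space mode.

    Windows from alternative TSSs of one gene are merged; any other gene's
    span truncates the window at its nearest boundary; coding exons of all
    genes (own gene included) are subtracted.  Genes may end with no region.
    """
    mode = SearchSpaceMode(mode)
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    result: dict[str, list[Region]] = {g.gene_id: [] for g in genes}
    for chrom, chrom_genes in by_chrom.items():
        exons = merge_intervals(
            [ex for g in chrom_genes for ex in g.coding_exons])
        for g in chrom_genes:
            windows = []
            for tss in g.tss_list:
                s, e = mode.window(tss, g.strand)
                if s < 0:
                    log.warning("%s: window start %d clipped to 0", g.gene_id, s)
                    s = 0
                if e > s:
                    windows.append((s, e))
            windows = merge_intervals(windows)
            neighbour_spans = [h.span for h in chrom_genes if h.gene_id != g.gene_id]
            windows = subtract_intervals(windows, neighbour_spans)
            windows = subtract_intervals(windows, exons)
            result[g.gene_id] = [
                Region(chrom, s, e, g.gene_id)
                for s, e in windows
                if e - s >= min_region_length
            ]
    return result


# ---------------------------------------------------------------------------
# I/O: annotation table, minimal GFF3, BED output
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "strand", "tx_start", "tx_end", "tss", "cds_exons",
]


def _parse_exons(spec: str) -> list[Interval]:
    spec = (spec or "").strip()
    if not spec or spec == ".":
        return []
    out = []
    for part in spec.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def read_annotation_table(path_or_buf) -> list[GeneModel]:
    """Read the tab-separated annotation dialect.

    Columns: gene_id, chrom, strand, tx_start, tx_end, tss, cds_exons
    (comma list of ``start-end``; ``.`` for none).  One row per transcript;
    rows of the same gene are merged into one :class:`GeneModel`.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        rec = genes.setdefault(gid, {
            "chrom": row.chrom, "strand": row.strand,
            "start": int(row.tx_start), "end": int(row.tx_end),
            "tss": set(), "exons": [],
        })
        if rec["chrom"] != row.chrom:
            raise ValueError(f"{gid}: transcripts on different chromosomes")
        rec["start"] = min(rec["start"], int(row.tx_start))
        rec["end"] = max(rec["end"], int(row.tx_end))
        rec["tss"].add(int(row.tss))
        rec["exons"].extend(_parse_exons(row.cds_exons))
    out = []
    for gid, rec in genes.items():
        for s, e in rec["exons"]:
            if s < rec["start"] or e > rec["end"]:
                raise ValueError(f"{gid}: coding exon ({s},{e}) outside gene span")
        out.append(GeneModel(
            gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
            span=(rec["start"], rec["end"]),
            tss_list=sorted(rec["tss"]),
            coding_exons=merge_intervals(rec["exons"]),
        ))
    return out


def write_annotation_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        exons = ",".join(f"{s}-{e}" for s, e in g.coding_exons) or "."
        for tss in g.tss_list:
            rows.append((g.gene_id, g.chrom, g.strand,
                         g.span[0], g.span[1], tss, exons))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gff3(path_or_buf) -> list[GeneModel]:
    """Minimal GFF3 subset: ``gene``, ``mRNA`` (Parent=gene) and ``CDS``
    (Parent=mRNA) features.  TSS = strand-aware 5' end of each mRNA.
    GFF coordinates (1-based closed) are converted to 0-based half-open.
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()

    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        start0, end0 = int(start) - 1, int(end)
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = {"chrom": chrom, "strand": strand,
                          "span": (start0, end0), "tss": set(), "exons": []}
        elif ftype == "mRNA":
            gid = attr["Parent"]
            mrna_to_gene[attr["ID"]] = gid
            if gid not in genes:
                raise ValueError(f"mRNA {attr['ID']} references unknown gene {gid}")
            tss = start0 if strand == "+" else end0
            genes[gid]["tss"].add(tss)
        elif ftype == "CDS":
            gid = mrna_to_gene.get(attr["Parent"], attr["Parent"])
            if gid not in genes:
                raise ValueError(f"CDS references unknown parent {attr['Parent']}")
            if chrom != genes[gid]["chrom"]:
                raise ValueError(f"CDS of {gid} on unexpected chromosome {chrom}")
            genes[gid]["exons"].append((start0, end0))
    out = []
    for gid, rec in genes.items():
        tss = sorted(rec["tss"]) or [rec["span"][0] if rec["strand"] == "+"
                                     else rec["span"][1]]
        out.append(GeneModel(
            gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
            span=rec["span"], tss_list=tss,
            coding_exons=merge_intervals(rec["exons"]),
        ))
    return out


def regions_to_bed(regions: dict[str, list[Region]]) -> pd.DataFrame:
    """Flatten delineated regions into a 6-column BED frame (name=gene_id)."""
    rows = []
    for gid in sorted(regions):
        for i, r in enumerate(regions[gid]):
            rows.append((r.chrom, r.start, r.end, gid, i, "+"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_regions_bed(regions: dict[str, list[Region]], path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)
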