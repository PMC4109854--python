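"""Delineate regulatory search spaces around genes.

Builds a three-gene annotation in which one gene sits inside another gene's
upstream window and one window contains a coding exon, then prints the
regions each search-space mode produces.
"""

from regulonscan import GeneModel, SearchSpaceMode, delineate_search_space

genes = [
    GeneModel("geneA", "chr1", "+", span=(100_000, 104_000),
              tss_list=[100_000, 100_800],
              coding_exons=[(100_200, 100_400)]),
    GeneModel("geneB", "chr1", "-", span=(96_000, 99_700), tss_list=[99_700]),
    GeneModel("geneC", "chr1", "+", span=(140_000, 142_000),
              tss_list=[140_000]),
]

for mode in SearchSpaceMode:
    regions = delineate_search_space(genes, mode)
    print(f"\n== {mode.value} (window {mode.window_length} bp per TSS) ==")
    for gid, regs in regions.items():
        spans = ", ".join(f"[{r.start:,}-{r.end:,})" for r in regs) or "none"
        print(f"  {gid}: {spans}")

print("""
geneA's upstream window is truncated where its neighbour geneB ends
(99,700), its two TSS windows merge when they overlap, and the coding exon
[100,200-100,400) is punched out of the larger windows — so one gene can
contribute several disjoint regions, or none at all.""")
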