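"""Map enriched motifs to candidate transcription factors.

Encodes a small association graph — direct motif-TF annotations, TF-TF
homology with percent identity, motif-motif similarity with p-values — and
ranks the candidate TFs for two query motifs.
"""

from regulonscan import Motif2TFGraph, map_motif_to_tfs, motif_similarity
from regulonscan.motif2tf import candidates_to_frame

g = Motif2TFGraph()
# M1 is unannotated but resembles two annotated motifs
g.add_similarity("M1", "M3", p_value=5e-4)
g.add_similarity("M1", "M4", p_value=5e-4)
g.add_annotation("M4", "TF1", species="human")
g.add_annotation("M3", "TF7", species="other")   # non-human annotation
for tf, ident in [("TF1", 62.0), ("TF6", 55.0), ("TF8", 48.0)]:
    g.add_homology("TF7", tf, identity_pct=ident)
# M2 is annotated only in another species; TF2's gene is in the input set
g.add_annotation("M2", "TF5", species="other")
for tf, ident in [("TF2", 70.0), ("TF3", 64.0), ("TF4", 58.0)]:
    g.add_homology("TF5", tf, identity_pct=ident)

for motif, input_genes in [("M1", set()), ("M2", {"TF2"})]:
    print(f"\ncandidates for {motif} "
          f"(input set: {sorted(input_genes) or 'none'}):")
    cands = map_motif_to_tfs(motif, g, input_genes)
    print(candidates_to_frame(cands).to_string(index=False))

print("""
TF1 wins for M1 through the shortest, best path (one similarity edge to M4,
which is directly annotated); TF6/TF8 need an extra homology hop.  For M2
all three orthologs of TF5 qualify, but TF2 is promoted because its gene is
part of the input set.""")
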