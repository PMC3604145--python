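"""Candidate VDRE discovery with positive and negative controls.

Builds the known-VDRE half-site library, plants two of the packaged
candidate sites (a TIA1-style and a COPB2-style DR3 element) at their
reported TSS-relative positions, scrubs two housekeeping windows clean,
scans everything, and summarizes control performance.
"""

from vdresponse import build_motif_library, control_evaluation, load_fixture
from vdresponse.synthetic import PlantedVdre, gen_sequences, make_window_annotations
from vdresponse.vdre import scan_upstream

library, motifs = build_motif_library(
    load_fixture("known_vdres"), load_fixture("motif_defs")
)

genes = [("TIA1", "+"), ("COPB2", "-"), ("ACTB", "+"), ("GAPDH", "+")]
anns, lengths = make_window_annotations(genes, window=(30_000, 0))
planted = [
    PlantedVdre("TIA1", -19259, "GGTTCAagcAGTTCT"),
    PlantedVdre("COPB2", -28579, "TGAACTcttAGGTGA"),
]
seqset, truth = gen_sequences(
    anns, lengths, library, planted=planted, exclude=["ACTB", "GAPDH"],
    seed=1, motifs=motifs,
)

hits = scan_upstream(seqset, library, motifs, window=(30_000, 0))
for h in hits:
    print(f"{h.gene_id:6s} {h.position:>7d} {h.strand} {h.sequence} "
          f"-> {', '.join(sorted(h.sources))}")
# positions are the signed offset of the motif's 5' end from the TSS
# (negative = upstream, gene orientation)

summary = control_evaluation(
    ["TIA1", "COPB2"], ["ACTB", "GAPDH"], hits,
    annotated_genes=[g for g, _ in genes],
)
print(f"\npositive-control sensitivity: {summary.sensitivity:.1f}")
print(f"hits in housekeeping windows: {summary.negative_hit_count}")
# 1.0 and 0: every planted site found, scrubbed windows stay clean
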