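"""EASE-score gene-set over-representation.

Scores a 30-gene list against two gene sets in a 5,000-gene background:
one set overlaps the list heavily, the other not at all.  The EASE
score is the one-sided Fisher exact upper tail computed after removing
one gene from the overlap, so single-gene overlaps can never score.
"""

from vdresponse import ease_score, enrich_gene_sets

population = [f"G{i:05d}" for i in range(5_000)]
gene_list = population[:30]
gene_sets = {
    "immune_response": set(population[:25]) | set(population[100:115]),
    "unrelated_set": set(population[1000:1040]),
}

table = enrich_gene_sets(gene_list, gene_sets, population, p_thresh=0.05)
print(table.to_string(index=False))
# only the overlapping set survives the p<0.05 filter; ease_p is
# always >= fisher_p because of the one-gene penalty

print(f"\nsingle-gene overlap scores ease_p = "
      f"{ease_score(1, 30, 40, 5_000):.1f} (penalized to 1)")
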