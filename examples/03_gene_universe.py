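"""The analysis gene universe: polymerase-occupied genes that are longer
than 2 kb and at least 2 kb away from their nearest neighbor.

The length filter is strict (a 2000 bp gene fails); the gap filter is
inclusive (a 2000 bp gap passes); overlapping genes count as gap 0.
"""

import occudelta as od

genes = [
    od.GeneModel("okA", "chr1", 0, 3000, "+"),       # 3 kb, gap 2000 to okB
    od.GeneModel("okB", "chr1", 5000, 9000, "-"),
    od.GeneModel("tooShort", "chr1", 20000, 22000, "+"),   # exactly 2 kb: fails
    od.GeneModel("crowdedA", "chr1", 30000, 33000, "+"),   # gap 1000: both fail
    od.GeneModel("crowdedB", "chr1", 34000, 38000, "+"),
]
ann = od.GenomeAnnotation(genes=genes, chrom_sizes={"chr1": 50000})
occupied = {g.gene_id for g in genes}  # pretend all promoters have polymerase

universe = od.filter_gene_universe(ann, occupied)
print(universe.outcomes)
print(f"\nretained universe (n = {universe.n}):", universe.gene_ids)
print("okA/okB pass: 2000 bp apart satisfies the inclusive >= 2 kb gap rule;")
print("tooShort fails the strict > 2 kb length rule; the crowded pair fails on gap.")
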