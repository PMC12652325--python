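"""Scale-regions occupancy matrices and per-cluster metagene fold-change
profiles: the polymerase gene-body depletion that separates the clusters is
visible directly in the per-bin means.
"""

import numpy as np

import occudelta as od

design = od.SimulationDesign(n_genes=400, seed=7)
ann, truth = od.generate_annotation(design)
tracks, _, samples = od.simulate_chip_experiment(ann, truth, design)
normalized, _ = od.normalize_samples(tracks, samples)

uni = od.GeneUniverse(gene_ids=list(truth.intended_universe), outcomes=None)
layout = od.RegionLayout()  # 2 kb flanks in 50 bp bins, 100 body bins
by_key = {(s.modality, s.pair_id, s.genotype): s.sample_id for s in samples}
null_m = od.build_scaled_matrix(normalized[by_key[("polII", "p1", "null")]], uni, ann, layout)
wt_m = od.build_scaled_matrix(normalized[by_key[("polII", "p1", "WT")]], uni, ann, layout)
fc = od.pairwise_log2fc(null_m, wt_m, pair_id="p1")

fb = layout.flank_bins
print(f"matrix: {fc.values.shape[0]} genes x {fc.values.shape[1]} bins "
      f"({fb} upstream + {layout.body_bins} body + {fb} downstream)")
for label in ("I", "II", "III"):
    genes = [g for g in truth.cluster_genes(label) if g in fc.values.index]
    profile, n = od.metagene_profile(fc, gene_ids=genes)
    body = profile[fb : fb + layout.body_bins].mean()
    print(f"cluster {label:>3} (n={n:>3}): mean body log2FC = {body:+.2f}")
print("cluster III loses the most polymerase across the gene body,")
print("cluster II an intermediate amount, cluster I essentially none.")
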