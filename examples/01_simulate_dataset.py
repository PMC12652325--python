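"""Generate a small synthetic dataset and inspect its planted ground truth.

The generator emulates cortex ChIP-seq for three modalities (AFF4, total
RNA pol II, Ser2-phosphorylated RNA pol II) in 3 matched WT/null animal
pairs with spike-in chromatin, plus 6 RNA-seq replicates per genotype.
Three gene clusters with distinct differential-occupancy phenotypes are
planted, along with genes that deliberately violate each universe filter.
"""

import occudelta as od

design = od.SimulationDesign(n_genes=300, seed=11)
annotation, truth = od.generate_annotation(design)
tracks, true_factors, samples = od.simulate_chip_experiment(annotation, truth, design)
expression = od.simulate_rnaseq_counts(annotation, truth, design)

print(f"genes placed: {len(annotation)} on one chromosome of "
      f"{annotation.chrom_sizes['chr1']/1e6:.1f} Mb")
print("planted cluster sizes:", truth.labels.value_counts().to_dict())
print("planted filter violations:", truth.filter_reason.value_counts().drop("none").to_dict())
print(f"ChIP samples: {len(samples)} (target + spike-in track each); "
      f"RNA samples: {expression.counts.shape[1]}")
print("spike-in depth multipliers are planted, so the true per-sample scale")
print("factors are known, e.g.:", {k: round(v, 3) for k, v in list(true_factors.items())[:3]})
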