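# occudelta

Spike-in–normalized ChIP-seq differential occupancy analysis for matched
case/control designs, built around the question of how loss of a chromatin
regulator (a *null* genotype vs wild type) reshapes the binding of a
transcription factor and of RNA polymerase II across genes — at the promoter
(paused polymerase), across the gene body (elongating polymerase) and past
the transcription end site — and how those occupancy changes relate to gene
expression.

It is written for computational biologists analyzing ChIP-seq with exogenous
spike-in chromatin (e.g. *Drosophila* chromatin spiked into mouse samples)
in matched animal pairs, with companion RNA-seq. The package is a library
first (`import occudelta`), with narrative scripts in `examples/` and a thin
CLI (`occudelta run-all --config config.yaml`) for file-driven runs.

## The method

Given per-sample coverage tracks over a target genome and a spike-in genome,
a gene annotation, and a sample sheet of matched WT/null pairs per assay
modality:

1. **Spike-in normalization.** Within each modality, sample *i* gets scale
   factor `s_i = min_j(spike_j) / spike_i`, where `spike_i` is its spike-in
   fragment count; target coverage is multiplied by `s_i`. The sample with
   the fewest spike-in reads is the reference, and every other sample is
   scaled down — never inflated. (Mean- and fixed-reference conventions are
   available.)
2. **Gene universe.** A gene enters the analysis iff it is (i) polymerase
   occupied at the promoter window `[TSS−1 kb, TSS+1 kb)` in a quorum of
   wild-type replicates (from peak calls or a coverage threshold),
   (ii) strictly longer than 2 kb, and (iii) at least 2 kb from the nearest
   other gene (overlap counts as 0 gap).
3. **Scale-regions matrices.** Per sample, a genes × bins matrix: 2 kb
   flanks in 50 bp bins, the gene body resampled into 100 equal-width bins
   (exact length-weighted means), minus-strand genes flipped 5′→3′. Region
   summaries are window means at TSS (±250 bp), gene body, TES (±250 bp) and
   both flanks.
4. **Matched-pair fold changes.** Per animal pair and modality, cellwise
   `log2((null + δ)/(WT + δ))` with pseudocount δ = 1.
5. **Replicate selection and clustering.** Pairs are scored by mean
   |log2FC| (summed over modalities) and the top *n* (default 2 of 3) are
   kept. Per gene, the feature vector is the log2 median-across-selected-
   pairs null/WT ratio of the TSS, body and TES summaries for each ChIP
   modality (9 features), standardized; Ward-linkage agglomerative
   clustering is cut at k = 3. Clusters are labelled canonically by mean
   polymerase body change: **III** = most depleted, **I** = least, **II** =
   the rest.
6. **Median of ratios and correlations.** Per gene, the null/WT ratio is
   formed within each matched pair and summarized as the median across
   pairs — replicate-level consistency is preserved rather than pooled.
   Per cluster, Spearman's ρ (average-rank ties; exact/permutation P at
   small n, t-approximation above n = 25) correlates factor body change
   with polymerase body change and with RNA expression change (ratio of
   per-genotype mean RPM). The fraction of genes with median polymerase
   body ratio < 1 and a per-cluster Wilcoxon rank-sum comparison of
   gene-level mean expression (exact enumeration when both groups ≤ 8)
   complete the summary.

A deterministic synthetic-data generator (`occudelta.simulate`) plants all
of this structure — three clusters with distinct phenotypes, known spike-in
depth multipliers, genes that violate each universe filter, a tunable
within-cluster rank correlation and per-cluster expression effects — so the
entire pipeline is testable end to end with known truth.

## Worked example

```bash
python examples/05_cluster_and_correlate.py
```

```
universe: 540 genes (planted: 540)
selected matched pairs (largest null-vs-WT difference): ['p1', 'p3']
cluster sizes: {'II': 386, 'I': 134, 'III': 20}
adjusted Rand index vs planted clusters: 0.935
fraction of genes with polymerase body loss: 0.883

per-cluster Spearman correlations of median null/WT body ratios:
  cluster   I: AFF4 vs polII  rho = -0.047  P = 0.59  (n = 134)
  cluster  II: AFF4 vs polII  rho = -0.089  P = 0.08  (n = 386)
  cluster III: AFF4 vs polII  rho = +0.543  P = 0.016  (n = 20)
  ...
cluster expression comparison (gene-level mean RPM, rank-sum test):
         n_genes  median_ratio    pvalue
cluster
I            134      1.195705  0.000087
II           386      0.987981  0.949940
III           20      0.673223  0.013321
```

Reading the numbers: the recovered universe matches the planted one exactly;
clustering recovers the three planted phenotype groups almost perfectly
(ARI 0.935 at this small size); ~88% of universe genes lose polymerase in
the null; only the small, highly expressed cluster III couples the factor
change to the polymerase change (positive ρ), and it shows the strongest
expression decrease (median null/WT ratio 0.67).

The other examples cover dataset simulation (`01`), scale factors (`02`),
the universe filters (`03`), metagene fold-change profiles (`04`) and the
file-based pipeline with byte-identical reruns (`06`).

## Command-line use

```bash
occudelta simulate --n-genes 300 --seed 11 --outdir data/
occudelta run-all --config config.yaml     # or stage-by-stage:
occudelta normalize --config config.yaml
occudelta universe  --config config.yaml
occudelta matrix    --config config.yaml
occudelta cluster   --config config.yaml
occudelta correlate --config config.yaml
```

Every output TSV carries the configuration hash and seed in a header
comment; identical config + inputs reproduce identical bytes.

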