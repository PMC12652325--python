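# Methods

This note documents the models, conventions and free parameters behind
`occudelta`, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing its outputs.

## Coordinates and coverage

All coordinates are 0-based half-open (BED convention); GTF input (1-based,
end-inclusive) is converted on read. The TSS of a gene is its `start` on the
`+` strand and its `end` on the `−` strand; the TES is the opposite anchor.

Coverage is held as run-length data: per chromosome, a strictly increasing
edge array partitioning `[0, size)` plus one constant value per run. Window
statistics are computed from prefix-sums of run areas, so window means and
body-bin means are *exact* integrals, not approximations on a grid; this is
what makes the per-base brute-force oracle agree to 1e-9 and bedGraph
round trips lossless. Writing emits only non-zero runs with `repr` float
formatting (which round-trips IEEE doubles exactly).

Target and spike-in data live in separate namespaces with separate
chromosome-size maps and are never mixed in one coordinate space.

## Spike-in normalization

The scale factor of sample *i* within a modality group is
`s_i = ref / spike_i` with `ref = min_j spike_j` by default. The minimum
convention keeps all factors in (0, 1]: sparse samples are never inflated,
which avoids amplifying their noise. `mean` and `fixed` reference
conventions are provided because the arithmetic form of spike-in scaling is
a convention, not a derived quantity. Normalization groups are per modality,
since different antibodies receive different spike-in masses. Spike-in
fragment counts come from the sample sheet when recorded; otherwise they are
estimated as coverage area / fragment length (default 200 bp) — a documented
fallback, since the area estimate assumes a fragment length.

## Gene universe

Three filters, applied to wild-type data only (the universe must not depend
on the effect being measured):

* **occupied** — promoter window `[TSS − w, TSS + w)`, default `w` = 1000 bp,
  either overlapped by a peak call or with mean normalized coverage at least
  θ × the track's width-weighted median of non-zero coverage (θ = 2), in a
  quorum of replicates (default: majority). Window, θ and quorum are
  configuration; there is no canonical definition of "occupied".
* **length** — strictly greater than 2000 bp ("longer than 2 kb" read
  literally: a 2000 bp gene fails).
* **gap** — nearest other gene span on the same chromosome at least 2000 bp
  away ("at least" read inclusively: exactly 2000 bp passes). The gap is
  strand-blind and overlap counts as gap 0, because the filter exists to
  avoid coverage bleed-through, which ignores strand.

The neighbor search is sort-based (O(n log n)) and is tested for exact
agreement with an all-pairs oracle on random annotations.

## Scale-regions layout and summaries

Defaults: 2 kb flanks at 50 bp bins, 100 equal-width body bins, TSS/TES
summary half-widths 250 bp, pseudocount δ = 1.0. The exact layout used for
published heatmaps of this kind is rarely stated; these mirror common
scale-regions practice and are all adjustable in `RegionLayout`. Body bins
with fractional edges use length-weighted means, so the sum of body-bin
means × bin width conserves the total body coverage area exactly.
Minus-strand rows are reversed so column 0 is always 5′-most. Fold-change
matrices are `log2((null + δ)/(WT + δ))` cellwise; δ > 0 keeps zero-coverage
bins finite and bounded. Region summaries (TSS, body, TES, both flanks) are
window means with the body window excluding the TSS and TES windows; the
> 2 kb length filter guarantees a non-empty body window at the default
half-widths.

## Replicate selection, clustering, labels

Pairs are scored by mean |log2FC| over genes × bins, summed across
modalities, and the top `n_select` (default 2 of 3) are kept — a concrete
realization of "the replicates in which the null samples differ most from
wild type"; a Euclidean-norm score would rank almost identically and is a
one-line change. Clustering uses, per gene, the log2 of the
median-across-selected-pairs null/WT ratio of the TSS, body and TES
summaries per ChIP modality (9 features with three modalities), standardized
to zero mean and unit variance, under Ward linkage on Euclidean distance cut
at k = 3. Summaries rather than full 180-bin profiles are the default
feature set: they are robust, fast, and capture the three phenotypes;
full-profile clustering can be built from the matrices directly. Canonical
labels are assigned by mean polymerase gene-body log2FC (III = most
negative, I = least); an exact tie raises an error rather than silently
picking an order.

## Median of ratios and statistics

Per gene, `(null_i + δ)/(WT_i + δ)` within each matched pair *i*, then the
median across pairs (mean of the middle two for even counts). This keeps
replicate-level information: a gene scores as changed only if the change is
consistent across animal pairs. RNA replicates are not pair-matched, so the
expression ratio is formed from per-genotype means of RPM-normalized counts
(note that RPM is compositional: a genome-wide shift moves all ratios
toward 1 by the shift's library-size effect).

Spearman correlations use average ranks for ties. Two-sided P values: exact
permutation enumeration for n ≤ 9 (n! ≤ 362 880), a seeded Monte-Carlo
permutation test (19 999 resamples, +1-corrected) for 9 < n ≤ 25, and the
t-approximation above — full enumeration beyond n ≈ 9 is computationally
impossible, and at the cluster sizes where these correlations are
interesting the t-approximation is standard. The Wilcoxon rank-sum test
enumerates all C(n+m, n) group assignments exactly (tie-aware, via average
ranks) when both groups have ≤ 8 observations, and uses the normal
approximation with tie and continuity corrections otherwise; all-tied input
returns P = 1 with a warning.

## The synthetic-data generator

The generator emulates the *structure* of a cortex ChIP-seq + RNA-seq study:
3 matched WT/null pairs × 3 ChIP modalities (a transcription factor, total
polymerase, elongating polymerase) with spike-in tracks, and 6 RNA replicates
per genotype, on one chromosome (multi-chromosome generation is out of
scope). Per gene and component (TSS bell of width 150 bp discretized in
15 bp steps; uniform body; uniform TES window; for the factor, uniform 2 kb
flanks), fragment counts are negative binomial with mean
`depth × weight × mass × depth_multiplier × effect`, where `weight` is a
log-normal per-gene baseline (floored at 0.5), `mass` the per-modality
component mass (the polymerase TSS mass is 0.5 × pausing index, default 4 —
a visible promoter-proximal peak), `depth_multiplier` the planted per-sample
sequencing/IP depth, and `effect` the planted null/WT multiplier of that
gene's cluster. Coverage is deposited as run-length intervals
(count × fragment length spread over the component).

Planted structure and defaults:

* **Cluster proportions** 0.242 / 0.720 / 0.038 of the universe — a
  realistic class imbalance with one small cluster.
* **Effects** (multiplicative on region means; the underlying phenomenon is
  directional, so magnitudes are free parameters chosen to be recoverable at
  desk-scale depth): cluster I loses polymerase at the TSS only (0.6);
  cluster II loses polymerase at TSS/body/TES (0.6/0.6/0.6) and elongating
  polymerase mostly past the TES (0.55); cluster III loses the factor at TSS
  and body (0.55) and both polymerase forms across the body (0.42–0.5).
  Per-gene log2 spread around these means: `effect_sd` = 0.15 by default.
* **Mixed-sign factor flank effects** in clusters I and II: ±0.4 log2 with
  zero mean, a planted assumption standing in for an unquantified mixture of
  increases and decreases at the flanks.
* **Planted rank correlation.** Within a cluster, body effects of the factor
  and the polymerases share a per-gene latent Gaussian score. The latent
  correlation is the Gaussian-copula inversion `2·sin(π·ρ/6)` of the target
  Spearman ρ, inflated by the closed-form attenuation from counting noise on
  median-of-pairs log ratios (NB noise at the design's typical weight), so
  the *planted* value refers to the measurable correlation. Default:
  ρ = 0.35 in cluster III, 0 elsewhere. The `correlation_design` factory
  (all-cluster-III, depth 300, effect spread 0.5 log2) keeps attenuation
  below ~15%, and its panel-mean recovery is verified in the tests.
* **Filter violations** are planted as exact counts: short genes (≤ 2 kb),
  adjacent pairs with < 2 kb internal gaps (placed so only the pair fails),
  and genes with no ChIP signal at all (fail occupancy). Universe genes are
  placed with ≥ 2 kb gaps and lengths ≥ 3 kb, so the intended universe is
  recovered exactly.
* **RNA-seq**: negative binomial, genotype multipliers 1.05 / 0.85 / 0.60
  for clusters I/II/III, cluster III baseline boosted 3× (the small cluster
  is the most highly expressed).
* **Spike-in**: per-sample depth multipliers (1.0, 1.3, 0.8, 1.1, 0.9, 1.2)
  applied to both target means and spike-in counts; spike-in counts are
  noise-free by default (`spikein_noise=True` Poisson-samples them), so true
  scale factors are known exactly.

Every output is a pure function of (design, seed); sub-streams for
annotation, ChIP and RNA are derived from the single seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (mappability, GC bias,
duplicates), sequence content, irregular fragment-size distributions,
between-pair biological heterogeneity beyond counting noise, multiple
chromosomes, overlapping transcript isoforms, and any coupling between gene
length and expression. Recovery results (ARI ≥ 0.9 and the like) certify
the pipeline's correctness on data satisfying its model, not discovery power
on real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: 2000 genes for
cluster recovery (ARI and label agreement are stable well below that), 300
genes × 20 seeds for correlation recovery (panel-mean comparison; a single
seed's Spearman at n = 300 has sampling SD ≈ 0.06, so per-seed bands would
measure sampling noise, not calibration), 1500 genes for the
fraction-decreased design. Oracle comparisons use 1e-9 absolute tolerance
(exact arithmetic up to float error). Pseudocounts: δ = 1 for fold changes
and ratio summaries in the pipeline; the correlation-recovery measurement
uses δ = 0.01 because a large δ shrinks ratios gene-dependently (low-coverage
genes shrink more), which would perturb ranks and attenuate the planted
correlation. Degenerate inputs fail loudly: zero spike-in counts, empty
universes, non-finite features, tied label statistics and window collisions
all raise named errors rather than proceeding.

## Known limitations

* The occupancy threshold rule depends on a genome-wide median of non-zero
  coverage, which is sensible for sparse ChIP tracks but not for
  near-uniform ones.
* RPM expression ratios are compositional (see above); no attempt is made at
  DESeq2-style size factors — differential-expression modeling is out of
  scope.
* The Monte-Carlo Spearman P (9 < n ≤ 25) has resolution 1/20 000.
* BAM ingestion is an extension point, not core: coverage arrives as
  bedGraph (or is generated), already fragment-resolved.
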