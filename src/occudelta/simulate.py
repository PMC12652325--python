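"""Deterministic synthetic-data generator with a planted three-cluster
structure.

The generator emulates cortex ChIP-seq for three modalities (AFF4, total RNA
pol II, Ser2-phosphorylated RNA pol II) in matched WT/null animal pairs,
with exogenous spike-in chromatin at known per-sample depths, plus RNA-seq
replicates per genotype. Every quantity downstream code estimates is known
by construction:

* the intended analysis universe (genes failing the length, neighbor-gap or
  polymerase-occupancy filters are planted explicitly);
* three gene clusters with distinct differential-occupancy phenotypes —
  cluster I loses polymerase only at the TSS, cluster II loses polymerase at
  the TSS, across the body and past the TES (with elongating polymerase lost
  mostly past the TES), and cluster III (small, highly expressed) loses the
  factor and both polymerase forms across the gene body;
* per-sample spike-in depth multipliers, hence true scale factors;
* a planted within-cluster rank correlation between factor and polymerase
  gene-body changes, realized through a shared per-gene latent score (the
  latent correlation is inflated analytically to offset counting-noise
  attenuation, so the planted value refers to the measurable correlation);
* per-cluster expression multipliers for the RNA-seq counts.

Fragment counts are negative binomial around closed-form means
(depth x gene weight x component mass x sample depth multiplier x effect),
deposited as run-length coverage: a discretized bell at the TSS, uniform
coverage over the body and a TES window, and — for the factor modality —
uniform flanking components upstream of the TSS and downstream of the TES.
Effect magnitudes are free parameters (the underlying study reports
directions, not magnitudes); defaults are documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    GenomeAnnotation,
    SampleMetadata,
    ValidationError,
)

LN2 = math.log(2.0)

#: default null/WT multipliers per cluster -> modality -> region; absent
#: entries are 1.0 (no change). Directions mirror the three phenotypes;
#: magnitudes are free parameters chosen to be recoverable at desk scale.
DEFAULT_EFFECTS: Dict[str, Dict[str, Dict[str, float]]] = {
    "I": {"polII": {"tss": 0.6}},
    "II": {
        "polII": {"tss": 0.6, "body": 0.6, "tes": 0.6},
        "pS2polII": {"body": 0.85, "tes": 0.55, "down": 0.55},
    },
    "III": {
        "AFF4": {"tss": 0.55, "body": 0.55},
        "polII": {"tss": 0.5, "body": 0.42, "tes": 0.45},
        "pS2polII": {"body": 0.45, "tes": 0.45, "down": 0.45},
    },
}

#: expected fragment mass per component at weight 1, relative to design.depth
#: (the polII TSS mass is pausing_index * 0.5, set in component_masses()).
BASE_MASSES: Dict[str, Dict[str, float]] = {
    "AFF4": {"up": 0.4, "tss": 0.4, "body": 0.6, "tes": 0.3, "down": 0.4},
    "polII": {"tss": 1.0, "body": 1.0, "tes": 0.4},
    "pS2polII": {"tss": 0.15, "body": 1.0, "tes": 0.5, "down": 0.3},
}

REGION_COMPONENTS = ("up", "tss", "body", "tes", "down")

# variance of the median of n iid normals, relative to one draw
_MEDIAN_VAR = {1: 1.0, 2: 0.5, 3: 0.449, 4: 0.298, 5: 0.287}


@dataclass(frozen=True)
class SimulationDesign:
    """All knobs of the generator; outputs are pure functions of this + seed."""

    n_genes: int = 2000
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: Optional[int] = None  # autosized when None
    cluster_proportions: Tuple[Tuple[str, float], ...] = (("I", 0.242), ("II", 0.720), ("III", 0.038))
    fraction_short: float = 0.03  # genes planted with length <= 2 kb
    fraction_close: float = 0.03  # genes planted in < 2 kb-gap pairs
    fraction_unoccupied: float = 0.04  # genes planted without polymerase signal
    n_pairs: int = 3
    modalities: Tuple[str, ...] = ("AFF4", "polII", "pS2polII")
    depth: float = 250.0  # expected body fragments per gene at weight 1
    fragment_length: int = 200
    dispersion: float = 0.01  # NB: var = mu + dispersion * mu^2
    pausing_index: float = 4.0  # polII TSS mass = 0.5 * pausing_index
    effect_sd: float = 0.15  # per-gene log2 spread of planted effects
    aff4_flank_sd: float = 0.4  # mixed-sign factor flank effect (clusters I, II)
    cluster_rho: Tuple[Tuple[str, float], ...] = (("I", 0.0), ("II", 0.0), ("III", 0.35))
    effects: Optional[Dict[str, Dict[str, Dict[str, float]]]] = None  # None -> DEFAULT_EFFECTS
    # gene geometry
    length_log_mean: float = math.log(9000.0)
    length_log_sd: float = 0.45
    min_length: int = 3000
    max_length: int = 40000
    gap_scale: float = 3000.0  # gaps = 2000 + Exp(gap_scale)
    weight_log_sd: float = 0.4
    min_weight: float = 0.5
    max_weight: float = 4.0
    cluster3_weight_boost: float = 2.0  # highest binding/expression in cluster III
    # spike-in
    spikein_base: int = 20000
    spikein_multipliers: Tuple[float, ...] = (1.0, 1.3, 0.8, 1.1, 0.9, 1.2)
    spikein_noise: bool = False  # Poisson-sample the spike-in counts
    spikein_chrom: str = "spike_chr1"
    spikein_chrom_length: int = 100_000
    # RNA-seq
    rna_n_reps: int = 6
    rna_depth: float = 200.0
    rna_dispersion: float = 0.05
    rna_multipliers: Tuple[Tuple[str, float], ...] = (("I", 1.05), ("II", 0.85), ("III", 0.60))
    cluster3_expression_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.depth <= 0 or self.rna_depth <= 0:
            raise ValidationError("sequencing depth must be positive")
        if self.dispersion <= 0 or self.rna_dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        props = dict(self.cluster_proportions)
        if any(p < 0 for p in props.values()) or sum(props.values()) <= 0:
            raise ValidationError("cluster proportions must be non-negative and not all zero")
        if any(m <= 0 for m in self.spikein_multipliers):
            raise ValidationError("spike-in multipliers must be positive")

    @property
    def proportions(self) -> Dict[str, float]:
        props = dict(self.cluster_proportions)
        total = sum(props.values())
        return {k: v / total for k, v in props.items()}

    @property
    def rho(self) -> Dict[str, float]:
        return dict(self.cluster_rho)

    @property
    def effect_table(self) -> Dict[str, Dict[str, Dict[str, float]]]:
        return self.effects if self.effects is not None else DEFAULT_EFFECTS

    def component_masses(self) -> Dict[str, Dict[str, float]]:
        masses = {m: dict(BASE_MASSES[m]) for m in self.modalities}
        if "polII" in masses:
            masses["polII"]["tss"] = 0.5 * self.pausing_index
        return masses


@dataclass
class ClusterTruth:
    """Ground truth of one generated dataset."""

    labels: pd.Series  # gene -> I | II | III | filtered
    baseline_weight: pd.Series
    latent: pd.Series  # per-gene latent effect score (shared across modalities)
    multipliers: Dict[str, pd.DataFrame]  # modality -> genes x regions null/WT multiplier
    intended_universe: List[str]
    filter_reason: pd.Series  # none | short | close | unoccupied
    true_scale_factors: Dict[str, float] = field(default_factory=dict)

    def cluster_genes(self, label: str) -> List[str]:
        return list(self.labels.index[self.labels == label])


def _latent_rho(design: SimulationDesign, rho_s: float) -> float:
    """Latent Gaussian correlation that realizes a target rank correlation.

    Inverts the Gaussian-copula relation rho_s = (6/pi) asin(rho/2) and
    inflates for attenuation by counting noise on median-of-pairs log ratios
    (closed-form NB noise at the design's typical gene weight of 1).
    """
    if rho_s == 0:
        return 0.0
    rho_gauss = 2.0 * math.sin(math.pi * rho_s / 6.0)
    masses = design.component_masses()
    med_factor = _MEDIAN_VAR.get(design.n_pairs, math.pi / (2 * design.n_pairs))
    rels = []
    for modality in ("AFF4", "polII"):
        if modality not in masses:
            continue
        mean_count = design.depth * masses[modality]["body"]
        var_pair = 2.0 * (1.0 / mean_count + design.dispersion) / LN2**2
        var_med = var_pair * med_factor
        rels.append(design.effect_sd**2 / (design.effect_sd**2 + var_med))
    attenuation = math.sqrt(np.prod(rels)) if rels else 1.0
    if attenuation <= 0:  # no planted effect spread: nothing to correlate
        return min(0.999, rho_gauss)
    return min(0.999, rho_gauss / attenuation)


# ---------------------------------------------------------------------------
# annotation + truth
# ---------------------------------------------------------------------------

def generate_annotation(design: SimulationDesign) -> Tuple[GenomeAnnotation, ClusterTruth]:
    """Place genes on one chromosome and fix all per-gene ground truth.

    Universe genes are separated by >= 2 kb gaps and are longer than 2 kb;
    planted filter violations are exact counts (``fraction_short`` genes of
    length <= 2 kb, ``fraction_close`` genes in adjacent pairs with < 2 kb
    internal gaps, ``fraction_unoccupied`` genes that will carry no
    polymerase signal).
    """
    rng = np.random.default_rng([design.seed, 11])
    n = design.n_genes
    n_short = int(round(design.fraction_short * n))
    n_close = 2 * (int(round(design.fraction_close * n)) // 2)
    n_unocc = int(round(design.fraction_unoccupied * n))
    n_universe = n - n_short - n_close - n_unocc
    if n_universe < 3:
        raise ValidationError("filter fractions leave fewer than 3 universe genes")

    # cluster labels for universe genes: exact planted counts, largest first
    props = design.proportions
    counts = {k: int(math.floor(p * n_universe)) for k, p in props.items()}
    leftover = n_universe - sum(counts.values())
    for k in sorted(props, key=lambda k: -props[k]):
        if leftover == 0:
            break
        counts[k] += 1
        leftover -= 1
    universe_labels = np.array([lab for lab, c in counts.items() for _ in range(c)])
    rng.shuffle(universe_labels)

    reasons = (
        ["none"] * n_universe + ["short"] * n_short + ["close"] * n_close + ["unoccupied"] * n_unocc
    )
    labels = list(universe_labels) + ["filtered"] * (n - n_universe)
    reasons = np.array(reasons)
    labels = np.array(labels)

    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    # lengths
    lengths = np.empty(n, dtype=np.int64)
    normal = reasons != "short"
    lengths[normal] = np.clip(
        np.exp(rng.normal(design.length_log_mean, design.length_log_sd, normal.sum())),
        design.min_length,
        design.max_length,
    ).astype(np.int64)
    lengths[~normal] = rng.integers(300, 2001, size=(~normal).sum())  # <= 2000 -> fails strict filter

    # chromosome order: shuffle all genes, but close-pair genes must be adjacent
    close_idx = np.flatnonzero(reasons == "close")
    other_idx = np.flatnonzero(reasons != "close")
    rng.shuffle(other_idx)
    slots: List[List[int]] = [[i] for i in other_idx]
    for a, b in zip(close_idx[0::2], close_idx[1::2]):
        slots.insert(int(rng.integers(0, len(slots) + 1)), [int(a), int(b)])

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    pos = 4000  # leading margin so flanks stay on-chromosome
    for slot in slots:
        for j, idx in enumerate(slot):
            if j > 0:  # internal gap of a planted close pair: < 2 kb
                pos += int(rng.integers(200, 1900))
            starts[idx] = pos
            ends[idx] = pos + lengths[idx]
            pos = int(ends[idx])
        pos += 2000 + int(rng.exponential(design.gap_scale))
    genome_len = pos + 4000
    if design.chrom_length is not None:
        if design.chrom_length < genome_len:
            raise ValidationError(
                f"chrom_length {design.chrom_length} too small; need >= {genome_len}"
            )
        genome_len = design.chrom_length

    strands = rng.choice(["+", "-"], size=n)
    genes = [
        GeneModel(gene_id=gene_ids[i], chrom=design.chrom, start=int(starts[i]), end=int(ends[i]), strand=str(strands[i]))
        for i in range(n)
    ]
    genes.sort(key=lambda g: g.start)
    annotation = GenomeAnnotation(
        genes=genes, chrom_sizes={design.chrom: int(genome_len)}, namespace="target"
    )

    # per-gene weights, latent scores and effect multipliers
    weights = np.clip(
        np.exp(rng.normal(0.0, design.weight_log_sd, n)), design.min_weight, design.max_weight
    )
    weights[labels == "III"] *= design.cluster3_weight_boost
    latent = rng.normal(size=n)

    effects = design.effect_table
    rho = design.rho
    multipliers: Dict[str, pd.DataFrame] = {}
    for modality in design.modalities:
        log2mult = np.zeros((n, len(REGION_COMPONENTS)))
        v_body = rng.normal(size=n)  # modality-private body spread
        v_tss = rng.normal(size=n)
        v_tes = rng.normal(size=n)
        for ci, cname in enumerate(("I", "II", "III")):
            mask = labels == cname
            if not mask.any():
                continue
            base = effects.get(cname, {}).get(modality, {})
            a = math.sqrt(_latent_rho(design, rho.get(cname, 0.0)))
            b = math.sqrt(1.0 - a * a)
            for ri, region in enumerate(REGION_COMPONENTS):
                col = np.full(mask.sum(), math.log2(base.get(region, 1.0)))
                if region == "body":
                    col = col + design.effect_sd * (a * latent[mask] + b * v_body[mask])
                elif region == "tss":
                    col = col + design.effect_sd * v_tss[mask]
                elif region == "tes":
                    col = col + design.effect_sd * v_tes[mask]
                log2mult[mask, ri] = col
        if modality == "AFF4" and design.aff4_flank_sd > 0:
            # mixed-sign flank effects with zero mean (clusters I and II)
            sign = rng.choice([-1.0, 1.0], size=n)
            for cname in ("I", "II"):
                mask = labels == cname
                for region in ("up", "down"):
                    ri = REGION_COMPONENTS.index(region)
                    log2mult[mask, ri] += sign[mask] * design.aff4_flank_sd
        multipliers[modality] = pd.DataFrame(
            np.exp2(log2mult), index=list(gene_ids), columns=list(REGION_COMPONENTS)
        )
        multipliers[modality].loc[labels == "filtered"] = 1.0

    truth = ClusterTruth(
        labels=pd.Series(labels, index=list(gene_ids), name="cluster"),
        baseline_weight=pd.Series(weights, index=list(gene_ids), name="weight"),
        latent=pd.Series(latent, index=list(gene_ids), name="latent"),
        multipliers=multipliers,
        intended_universe=[gid for gid, r in zip(gene_ids, reasons) if r == "none"],
        filter_reason=pd.Series(reasons, index=list(gene_ids), name="filter_reason"),
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def _component_window(gene: GeneModel, component: str, tes_halfwidth: int = 250, flank: int = 2000):
    """Genomic (start, end) of a deposit component, oriented by strand."""
    if component == "body":
        return gene.start, gene.end
    if component == "tes":
        return gene.tes - tes_halfwidth, gene.tes + tes_halfwidth
    if gene.strand == "+":
        if component == "up":
            return gene.start - flank, gene.start
        if component == "down":
            return gene.end, gene.end + flank
    else:
        if component == "up":
            return gene.end, gene.end + flank
        if component == "down":
            return gene.start - flank, gene.start
    raise ValueError(component)


_BELL_STEPS = 10
_BELL_WIDTH = 150  # bp


def _bell_weights() -> np.ndarray:
    centers = (np.arange(_BELL_STEPS) + 0.5) / _BELL_STEPS - 0.5  # in (-0.5, 0.5)
    w = np.exp(-0.5 * (centers / 0.25) ** 2)
    return w / w.sum()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 1e-9:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_chip_experiment(
    annotation: GenomeAnnotation,
    truth: ClusterTruth,
    design: SimulationDesign,
) -> Tuple[Dict[str, Tuple[CoverageTrack, CoverageTrack]], Dict[str, float], List[SampleMetadata]]:
    """Simulate target + spike-in coverage for every ChIP sample.

    Returns (tracks, true_scale_factors, samples) where ``tracks`` maps
    sample_id to its (target, spikein) pair and ``true_scale_factors`` holds
    min(multiplier)/multiplier per sample — the factors spike-in
    normalization should recover.
    """
    if design.depth <= 0:
        raise ValidationError("zero sequencing depth")
    rng = np.random.default_rng([design.seed, 23])
    masses = design.component_masses()
    bell_w = _bell_weights()
    genes = annotation.genes
    gene_ids = [g.gene_id for g in genes]
    weights = truth.baseline_weight.loc[gene_ids].to_numpy()
    unoccupied = (truth.filter_reason.loc[gene_ids] == "unoccupied").to_numpy()

    n_samples_per_mod = design.n_pairs * 2
    mults = list(design.spikein_multipliers)
    while len(mults) < n_samples_per_mod:
        mults += mults
    mults = np.array(mults[:n_samples_per_mod], dtype=float)
    min_mult = mults.min()

    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]] = {}
    true_factors: Dict[str, float] = {}
    samples: List[SampleMetadata] = []
    spike_sizes = {design.spikein_chrom: design.spikein_chrom_length}

    for modality in design.modalities:
        mult_table = truth.multipliers[modality].loc[gene_ids]
        si = 0
        for pair in range(1, design.n_pairs + 1):
            for genotype in ("WT", "null"):
                sample_id = f"{modality}_p{pair}_{genotype}"
                depth_mult = mults[si]
                starts: List[int] = []
                ends: List[int] = []
                values: List[float] = []
                for component, mass in masses[modality].items():
                    eff = mult_table[component].to_numpy() if genotype == "null" else 1.0
                    mean = design.depth * weights * mass * depth_mult * eff
                    mean = np.where(unoccupied, 0.0, mean)
                    counts = _nb_draw(rng, mean, design.dispersion)
                    for g, c in zip(genes, counts):
                        if c == 0:
                            continue
                        total = float(c * design.fragment_length)
                        if component == "tss":
                            step = _BELL_WIDTH // _BELL_STEPS
                            left = g.tss - _BELL_WIDTH // 2
                            for j in range(_BELL_STEPS):
                                starts.append(left + j * step)
                                ends.append(left + (j + 1) * step)
                                values.append(total * bell_w[j] / step)
                        else:
                            lo, hi = _component_window(g, component)
                            starts.append(lo)
                            ends.append(hi)
                            values.append(total / (hi - lo))
                target = CoverageTrack.from_intervals(
                    sample_id=sample_id,
                    namespace="target",
                    chrom_sizes=annotation.chrom_sizes,
                    intervals={
                        design.chrom: (np.array(starts), np.array(ends), np.array(values))
                    },
                )
                spike_n = design.spikein_base * depth_mult
                spike_n = int(rng.poisson(spike_n)) if design.spikein_noise else int(round(spike_n))
                spike_cov = spike_n * design.fragment_length / design.spikein_chrom_length
                spike = CoverageTrack(
                    sample_id=sample_id,
                    namespace="spikein",
                    chrom_sizes=dict(spike_sizes),
                    data={
                        design.spikein_chrom: (
                            np.array([0, design.spikein_chrom_length], dtype=np.int64),
                            np.array([spike_cov]),
                        )
                    },
                    total_fragments=spike_n,
                )
                tracks[sample_id] = (target, spike)
                true_factors[sample_id] = float(min_mult / depth_mult)
                samples.append(
                    SampleMetadata(
                        sample_id=sample_id,
                        genotype=genotype,
                        modality=modality,
                        pair_id=f"p{pair}",
                        spikein_fragments=spike_n,
                    )
                )
                si += 1
    return tracks, true_factors, samples


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_rnaseq_counts(
    annotation: GenomeAnnotation, truth: ClusterTruth, design: SimulationDesign
) -> ExpressionTable:
    """Negative-binomial gene counts, ``rna_n_reps`` replicates per genotype.

    Null-genotype means are multiplied per cluster (defaults: I slightly up,
    II down, III strongly down); cluster III has the highest baseline
    expression.
    """
    if design.rna_dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    rng = np.random.default_rng([design.seed, 37])
    gene_ids = [g.gene_id for g in annotation.genes]
    weights = truth.baseline_weight.loc[gene_ids].to_numpy()
    labels = truth.labels.loc[gene_ids].to_numpy()
    base = design.rna_depth * weights
    base = np.where(labels == "III", base * design.cluster3_expression_boost, base)
    rna_mult = dict(design.rna_multipliers)
    null_mult = np.array([rna_mult.get(lab, 1.0) for lab in labels])

    cols = {}
    genotypes = {}
    for genotype in ("WT", "null"):
        mean = base * (null_mult if genotype == "null" else 1.0)
        for rep in range(1, design.rna_n_reps + 1):
            sid = f"RNA_{genotype}_r{rep}"
            cols[sid] = _nb_draw(rng, mean, design.rna_dispersion)
            genotypes[sid] = genotype
    counts = pd.DataFrame(cols, index=gene_ids)
    return ExpressionTable(counts=counts, genotypes=genotypes)


# ---------------------------------------------------------------------------
# design factories for specific study conditions
# ---------------------------------------------------------------------------

def correlation_design(rho: float, n_genes: int = 300, seed: int = 0) -> SimulationDesign:
    """All-cluster-III design for rank-correlation recovery experiments.

    High depth and a wide per-gene effect spread keep counting-noise
    attenuation small, so the measured factor-vs-polymerase gene-body
    correlation reflects the planted value.
    """
    return replace(
        SimulationDesign(),
        n_genes=n_genes,
        seed=seed,
        cluster_proportions=(("III", 1.0),),
        cluster_rho=(("III", rho),),
        fraction_short=0.0,
        fraction_close=0.0,
        fraction_unoccupied=0.0,
        modalities=("AFF4", "polII"),
        depth=300.0,
        effect_sd=0.5,
        cluster3_weight_boost=1.0,
    )


def fraction_decreased_design(fraction: float = 0.9, n_genes: int = 1500, seed: int = 0) -> SimulationDesign:
    """Design planting an exact fraction of genes with polymerase body loss.

    Genes outside that fraction get a clear body *increase*, and the
    per-gene effect spread is kept small, so the planted fraction is the
    measurable one up to counting noise.
    """
    effects = {
        "I": {"polII": {"body": 1.4}},
        "II": {"polII": {"tss": 0.6, "body": 0.7, "tes": 0.7}},
        "III": {"polII": {"tss": 0.55, "body": 0.5, "tes": 0.5}},
    }
    return replace(
        SimulationDesign(),
        n_genes=n_genes,
        seed=seed,
        cluster_proportions=(("I", 1.0 - fraction), ("II", fraction - 0.038), ("III", 0.038)),
        cluster_rho=(("I", 0.0), ("II", 0.0), ("III", 0.0)),
        fraction_short=0.0,
        fraction_close=0.0,
        fraction_unoccupied=0.0,
        modalities=("polII",),
        effects=effects,
        effect_sd=0.05,
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(design: SimulationDesign, outdir) -> Dict[str, str]:
    """Generate a full dataset and write it through the public file formats.

    Writes the gene annotation (BED6), chromosome sizes, one target and one
    spike-in bedGraph per ChIP sample, the TSV sample sheet, the RNA count
    table and the planted truth table. Returns the path map.
    """
    from . import io as odio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_annotation(design)
    tracks, true_factors, samples = simulate_chip_experiment(annotation, truth, design)
    expression = simulate_rnaseq_counts(annotation, truth, design)

    paths = {
        "annotation": str(outdir / "genes.bed"),
        "chrom_sizes": str(outdir / "target.chrom.sizes"),
        "spike_chrom_sizes": str(outdir / "spikein.chrom.sizes"),
        "sample_sheet": str(outdir / "samples.tsv"),
        "counts": str(outdir / "rna_counts.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    odio.write_gene_annotation(annotation, paths["annotation"])
    odio.write_chrom_sizes(annotation.chrom_sizes, paths["chrom_sizes"])
    odio.write_chrom_sizes({design.spikein_chrom: design.spikein_chrom_length}, paths["spike_chrom_sizes"])

    sheet = []
    for s in samples:
        target, spike = tracks[s.sample_id]
        tpath = outdir / f"{s.sample_id}.target.bedgraph"
        spath = outdir / f"{s.sample_id}.spikein.bedgraph"
        odio.write_bedgraph(target, tpath)
        odio.write_bedgraph(spike, spath)
        sheet.append(
            SampleMetadata(
                sample_id=s.sample_id,
                genotype=s.genotype,
                modality=s.modality,
                pair_id=s.pair_id,
                target_path=tpath.name,
                spikein_path=spath.name,
                spikein_fragments=s.spikein_fragments,
            )
        )
    for genotype in ("WT", "null"):
        for rep in range(1, design.rna_n_reps + 1):
            sheet.append(
                SampleMetadata(sample_id=f"RNA_{genotype}_r{rep}", genotype=genotype, modality="RNA")
            )
    odio.write_sample_sheet(sheet, paths["sample_sheet"])
    odio.write_expression_table(expression, paths["counts"])

    truth_df = pd.DataFrame(
        {
            "cluster": truth.labels,
            "filter_reason": truth.filter_reason,
            "weight": truth.baseline_weight,
            "latent": truth.latent,
            "in_universe": truth.labels.index.isin(truth.intended_universe),
        }
    )
    truth_df.index.name = "gene_id"
    truth_df.to_csv(paths["truth"], sep="\t")
    pd.Series(true_factors, name="true_scale_factor").rename_axis("sample_id").to_csv(
        outdir / "true_scale_factors.tsv", sep="\t"
    )
    paths["true_scale_factors"] = str(outdir / "true_scale_factors.tsv")
    return paths
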