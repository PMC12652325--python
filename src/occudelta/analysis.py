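"""In-memory end-to-end analysis: the same stage sequence as the file-based
pipeline, operating on domain objects. This is the primary library entry
point; :mod:`occudelta.pipeline` wraps the same operations with file I/O for
shell use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cluster import (
    ClusterAssignment,
    CorrelationResult,
    PairedRatioSummary,
    build_cluster_features,
    cluster_genes,
    compare_cluster_expression,
    fraction_decreased,
    label_clusters,
    median_ratio_per_gene,
    rna_expression_ratios,
    select_pairs,
    spearman_by_cluster,
)
from .models import (
    CoverageTrack,
    ExpressionTable,
    GenomeAnnotation,
    RegionLayout,
    SampleMetadata,
    ValidationError,
)
from .occupancy import build_scaled_matrix, pairwise_log2fc, summarize_regions
from .spikenorm import SpikeInStats, compute_scale_factors, count_spikein_fragments, normalize_track
from .universe import GeneUniverse, detect_occupied_genes, filter_gene_universe


@dataclass
class AnalysisResult:
    """Everything the end-to-end analysis computes."""

    scale_factors: Dict[str, float]
    universe: GeneUniverse
    region_summaries: Dict[str, pd.DataFrame]  # sample_id -> per-gene summary
    selected_pairs: List[str]
    assignment: ClusterAssignment
    median_ratios: Dict[Tuple[str, str], PairedRatioSummary]  # (modality, region)
    correlations: List[CorrelationResult] = field(default_factory=list)
    fraction_polii_body_decreased: Optional[float] = None
    expression_comparison: Optional[pd.DataFrame] = None
    rna_ratios: Optional[pd.Series] = None


def normalize_samples(
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]],
    samples: Sequence[SampleMetadata],
    convention: str = "min",
    fragment_length: int = 200,
) -> Tuple[Dict[str, CoverageTrack], Dict[str, float]]:
    """Spike-in normalize every ChIP sample, grouped per modality."""
    factors: Dict[str, float] = {}
    by_mod: Dict[str, List[SampleMetadata]] = {}
    for s in samples:
        if s.modality != "RNA":
            by_mod.setdefault(s.modality, []).append(s)
    for group in by_mod.values():
        stats = []
        for s in sorted(group, key=lambda s: s.sample_id):
            if s.spikein_fragments is not None:
                n_spike = s.spikein_fragments
            else:
                n_spike = count_spikein_fragments(tracks[s.sample_id][1], fragment_length)
            stats.append(SpikeInStats(s.sample_id, s.target_fragments or 0, n_spike))
        for st in compute_scale_factors(stats, convention=convention):
            factors[st.sample_id] = st.scale_factor
    normalized = {
        s.sample_id: normalize_track(tracks[s.sample_id][0], factors[s.sample_id])
        for s in samples
        if s.modality != "RNA"
    }
    return normalized, factors


def analyze_experiment(
    annotation: GenomeAnnotation,
    tracks: Dict[str, Tuple[CoverageTrack, CoverageTrack]],
    samples: Sequence[SampleMetadata],
    expression: Optional[ExpressionTable] = None,
    layout: RegionLayout = RegionLayout(),
    ratio_pseudocount: float = 1.0,
    n_select: int = 2,
    k: int = 3,
    normalization: str = "min",
    occupied_threshold: float = 2.0,
    occupied_window: int = 1000,
    universe: Optional[GeneUniverse] = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full differential-occupancy analysis on in-memory objects.

    Stages: spike-in normalization, universe filtering (threshold occupancy
    on WT polymerase samples unless a universe is supplied), scale-regions
    matrices and per-pair fold changes, pair selection, clustering with
    canonical labels (k = 3), median-of-ratios summaries, per-cluster
    correlations, fraction-decreased and the cluster expression comparison.
    """
    chip = [s for s in samples if s.modality != "RNA"]
    modalities = sorted({s.modality for s in chip})
    pair_ids = sorted({s.pair_id for s in chip})
    normalized, factors = normalize_samples(tracks, samples, convention=normalization)

    if universe is None:
        wt_polii = [normalized[s.sample_id] for s in chip if s.modality == "polII" and s.genotype == "WT"]
        if not wt_polii:
            raise ValidationError("no WT polII samples: supply a universe explicitly")
        occupied = detect_occupied_genes(
            annotation,
            mode="threshold",
            tracks=wt_polii,
            threshold_multiple=occupied_threshold,
            window_halfwidth=occupied_window,
        )
        universe = filter_gene_universe(annotation, occupied)

    by_key = {(s.modality, s.pair_id, s.genotype): s.sample_id for s in chip}
    matrices = {
        s.sample_id: build_scaled_matrix(normalized[s.sample_id], universe, annotation, layout, s.modality)
        for s in chip
    }
    summaries = {
        s.sample_id: summarize_regions(normalized[s.sample_id], universe, annotation, layout)
        for s in chip
    }
    fcs = [
        pairwise_log2fc(matrices[by_key[(m, p, "null")]], matrices[by_key[(m, p, "WT")]], pair_id=p)
        for m in modalities
        for p in pair_ids
    ]
    selected = select_pairs(fcs, min(n_select, len(pair_ids)))

    ratio_summaries: Dict[Tuple[str, str], PairedRatioSummary] = {}
    for m in modalities:
        null_s = {p: summaries[by_key[(m, p, "null")]] for p in pair_ids}
        wt_s = {p: summaries[by_key[(m, p, "WT")]] for p in pair_ids}
        for region in ("tss", "body", "tes"):
            ratio_summaries[(m, region)] = median_ratio_per_gene(
                null_s, wt_s, m, region, pseudocount=ratio_pseudocount
            )

    features = build_cluster_features(ratio_summaries, selected, modalities=modalities)
    assignment = cluster_genes(features, k=k)
    assignment.selected_pairs = tuple(selected)
    if k == 3 and "polII" in modalities:
        polii_body = np.log2(ratio_summaries[("polII", "body")].ratios[selected].median(axis=1))
        assignment = label_clusters(assignment, polii_body)

    result = AnalysisResult(
        scale_factors=factors,
        universe=universe,
        region_summaries=summaries,
        selected_pairs=list(selected),
        assignment=assignment,
        median_ratios=ratio_summaries,
    )
    if "polII" in modalities:
        result.fraction_polii_body_decreased = fraction_decreased(
            ratio_summaries[("polII", "body")].median
        )
        if "AFF4" in modalities:
            result.correlations += spearman_by_cluster(
                ratio_summaries[("AFF4", "body")].median,
                ratio_summaries[("polII", "body")].median,
                assignment,
                "AFF4",
                "polII",
                seed=seed,
            )
    if expression is not None:
        rna = rna_expression_ratios(expression, pseudocount=ratio_pseudocount)
        result.rna_ratios = rna.loc[assignment.labels.index]
        if "AFF4" in modalities:
            result.correlations += spearman_by_cluster(
                ratio_summaries[("AFF4", "body")].median,
                result.rna_ratios,
                assignment,
                "AFF4",
                "RNA",
                seed=seed,
            )
        result.expression_comparison = compare_cluster_expression(
            expression, assignment, pseudocount=ratio_pseudocount
        )
    return result
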