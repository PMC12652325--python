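"""Replicate selection, hierarchical clustering of differential-occupancy
profiles, matched-pair median-of-ratios summaries, cluster-wise Spearman
correlations, fraction-decreased summaries and the cluster-expression
rank-sum comparison.

The clustering feature table is, per gene: the per-modality log2 of the
median (across the selected matched pairs) null/WT ratio of the TSS, body
and TES region summaries — nine features with three ChIP modalities — each
standardized to zero mean and unit variance. Agglomerative clustering (Ward
linkage, Euclidean distance) is cut at k = 3 and the clusters are labelled
canonically by their mean polymerase gene-body fold change: the most
depleted cluster is III, the least is I. Median-of-ratios keeps matched-pair
(animal pair) structure: one null/WT ratio per pair, then the median across
pairs, which preserves replicate-level consistency instead of pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .models import ExpressionTable, ValidationError
from .occupancy import FoldChangeMatrix
from .stats import TestResult, rank_sum_test, spearman_test

CANONICAL_LABELS = ("I", "II", "III")
CHIP_MODALITIES = ("AFF4", "polII", "pS2polII")
FEATURE_REGIONS = ("tss", "body", "tes")


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels plus the feature table that produced them."""

    labels: pd.Series  # index gene_id, values cluster labels
    features: pd.DataFrame = field(repr=False)
    linkage: str = "ward"
    metric: str = "euclidean"
    selected_pairs: Tuple[str, ...] = ()

    def genes_in(self, label: str) -> List[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> Dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class PairedRatioSummary:
    """Per-gene null/WT ratios per matched pair and their median."""

    modality: str
    region: str
    ratios: pd.DataFrame = field(repr=False)  # genes x pair_ids
    pseudocount: float = 1.0

    @property
    def median(self) -> pd.Series:
        return self.ratios.median(axis=1)


@dataclass(frozen=True)
class CorrelationResult:
    cluster: str
    x_modality: str
    y_modality: str
    rho: float
    pvalue: float
    n: int


# ---------------------------------------------------------------------------
# replicate (pair) selection
# ---------------------------------------------------------------------------

def select_pairs(fc_matrices: Sequence[FoldChangeMatrix], n_select: int) -> List[str]:
    """Choose the matched pairs whose null samples differ most from WT.

    Each pair is scored by the mean |log2FC| over all genes x bins, summed
    across the modalities present; the top ``n_select`` scores win, with
    ties broken by lexicographic pair_id.
    """
    scores: Dict[str, float] = {}
    for fc in fc_matrices:
        scores[fc.pair_id] = scores.get(fc.pair_id, 0.0) + float(np.abs(fc.values.to_numpy()).mean())
    if n_select > len(scores):
        raise ValidationError(f"cannot select {n_select} of {len(scores)} pairs")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return sorted(pid for pid, _ in ranked[:n_select])


# ---------------------------------------------------------------------------
# median of ratios
# ---------------------------------------------------------------------------

def median_ratio_per_gene(
    null_summaries: Dict[str, pd.DataFrame],
    wt_summaries: Dict[str, pd.DataFrame],
    modality: str,
    region: str,
    pseudocount: float = 1.0,
) -> PairedRatioSummary:
    """Per-pair (null + d)/(WT + d) ratios of a region summary, per gene.

    ``null_summaries`` / ``wt_summaries`` map pair_id to the per-gene region
    summary table of that pair's sample. Every pair must cover every gene.
    """
    pair_ids = sorted(null_summaries)
    if sorted(wt_summaries) != pair_ids or not pair_ids:
        raise ValidationError("null and WT summaries must cover the same non-empty pair set")
    cols = {}
    index = null_summaries[pair_ids[0]].index
    for pid in pair_ids:
        nd, wd = null_summaries[pid], wt_summaries[pid]
        if not nd.index.equals(index) or not wd.index.equals(index):
            raise ValidationError(f"pair {pid}: summaries do not cover the shared gene universe")
        cols[pid] = (nd[region] + pseudocount) / (wd[region] + pseudocount)
    ratios = pd.DataFrame(cols)
    return PairedRatioSummary(modality=modality, region=region, ratios=ratios, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def build_cluster_features(
    summaries: Dict[Tuple[str, str], PairedRatioSummary],
    selected_pairs: Sequence[str],
    modalities: Sequence[str] = CHIP_MODALITIES,
    regions: Sequence[str] = FEATURE_REGIONS,
) -> pd.DataFrame:
    """Assemble the gene x feature table: log2 median ratio per
    (modality, region), restricted to the selected matched pairs."""
    cols = {}
    for modality in modalities:
        for region in regions:
            summ = summaries[(modality, region)]
            sub = summ.ratios[list(selected_pairs)]
            cols[f"{modality}_{region}"] = np.log2(sub.median(axis=1))
    return pd.DataFrame(cols)


def cluster_genes(
    features: pd.DataFrame,
    k: int = 3,
    linkage: str = "ward",
    metric: str = "euclidean",
    standardize: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of the feature table, cut at k clusters.

    Features are standardized to zero mean, unit variance by default.
    Deterministic given the input row order. Raw labels are "C0", "C1", ...
    until :func:`label_clusters` assigns canonical names.
    """
    if not np.isfinite(features.to_numpy()).all():
        bad = features.index[~np.isfinite(features.to_numpy()).all(axis=1)]
        raise ValidationError(f"non-finite feature values for genes {list(bad[:5])}")
    if k > len(features):
        raise ValidationError(f"k={k} exceeds number of genes ({len(features)})")
    X = features.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage, metric=metric)
    raw = model.fit_predict(X)
    labels = pd.Series([f"C{int(c)}" for c in raw], index=features.index, name="cluster")
    return ClusterAssignment(labels=labels, features=features, linkage=linkage, metric=metric)


def label_clusters(
    assignment: ClusterAssignment, polii_body_log2fc: pd.Series
) -> ClusterAssignment:
    """Assign canonical labels I/II/III by mean polymerase gene-body change.

    III = most negative mean log2FC, I = least negative, II = the remainder.
    Only defined for k = 3; an exact tie in the ordering statistic raises
    (manual labelling is required rather than a silent arbitrary choice).
    """
    raw_labels = sorted(assignment.labels.unique())
    if len(raw_labels) != 3:
        raise ValidationError(f"canonical labelling requires exactly 3 clusters, got {len(raw_labels)}")
    means = {
        lab: float(polii_body_log2fc.loc[assignment.labels == lab].mean()) for lab in raw_labels
    }
    vals = sorted(means.values())
    if len(set(vals)) != 3:
        raise ValidationError("tied cluster means: canonical labelling is ambiguous, label manually")
    order = sorted(raw_labels, key=lambda lab: -means[lab])  # least negative first
    mapping = dict(zip(order, CANONICAL_LABELS))
    labels = assignment.labels.map(mapping)
    return ClusterAssignment(
        labels=labels,
        features=assignment.features,
        linkage=assignment.linkage,
        metric=assignment.metric,
        selected_pairs=assignment.selected_pairs,
    )


# ---------------------------------------------------------------------------
# correlations and summaries
# ---------------------------------------------------------------------------

def spearman_by_cluster(
    x: pd.Series,
    y: pd.Series,
    assignment: ClusterAssignment,
    x_modality: str = "AFF4",
    y_modality: str = "polII",
    seed: int = 0,
) -> List[CorrelationResult]:
    """Per-cluster Spearman correlation of two per-gene summaries."""
    results = []
    for label in sorted(assignment.labels.unique()):
        genes = assignment.genes_in(label)
        if len(genes) < 3:
            raise ValidationError(f"cluster {label} has fewer than 3 genes")
        missing = set(genes) - set(x.index) | set(genes) - set(y.index)
        if missing:
            raise ValidationError(f"summaries missing genes {sorted(missing)[:5]}")
        res: TestResult = spearman_test(x.loc[genes].to_numpy(), y.loc[genes].to_numpy(), seed=seed)
        results.append(
            CorrelationResult(
                cluster=label,
                x_modality=x_modality,
                y_modality=y_modality,
                rho=res.statistic,
                pvalue=res.pvalue,
                n=len(genes),
            )
        )
    return results


def fraction_decreased(median_ratios: pd.Series) -> float:
    """Fraction of genes with median null/WT ratio strictly below 1."""
    if len(median_ratios) == 0:
        raise ValidationError("empty universe")
    return float((median_ratios < 1.0).mean())


def rna_expression_ratios(
    expression: ExpressionTable, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene (mean null RPM + d)/(mean WT RPM + d).

    RNA replicates are not pair-matched; the ratio is formed from
    per-genotype replicate means of RPM-normalized expression.
    """
    rpm = expression.rpm()
    wt = rpm[expression.samples_of("WT")].mean(axis=1)
    null = rpm[expression.samples_of("null")].mean(axis=1)
    return (null + pseudocount) / (wt + pseudocount)


def compare_cluster_expression(
    expression: ExpressionTable,
    assignment: ClusterAssignment,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster WT vs null comparison of gene-level mean expression.

    For each cluster: per-gene mean RPM across replicates within each
    genotype, then a two-sided Wilcoxon rank-sum test between the WT and
    null gene-level mean vectors; also reports the cluster's median
    expression ratio as the direction of change.
    """
    rpm = expression.rpm()
    wt_cols = expression.samples_of("WT")
    null_cols = expression.samples_of("null")
    rows = []
    for label in sorted(assignment.labels.unique()):
        genes = [g for g in assignment.genes_in(label) if g in rpm.index]
        if len(genes) < 3:
            raise ValidationError(f"cluster {label} has fewer than 3 genes with expression data")
        wt_means = rpm.loc[genes, wt_cols].mean(axis=1)
        null_means = rpm.loc[genes, null_cols].mean(axis=1)
        res = rank_sum_test(wt_means.to_numpy(), null_means.to_numpy())
        ratio = (null_means + pseudocount) / (wt_means + pseudocount)
        rows.append(
            {
                "cluster": label,
                "n_genes": len(genes),
                "wt_mean_rpm": float(wt_means.mean()),
                "null_mean_rpm": float(null_means.mean()),
                "median_ratio": float(ratio.median()),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def correlation_table(results: List[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "x_modality": [r.x_modality for r in results],
            "y_modality": [r.y_modality for r in results],
            "rho": [r.rho for r in results],
            "pvalue": [r.pvalue for r in results],
            "n": [r.n for r in results],
        }
    ).set_index("cluster")
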