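"""Scale-regions occupancy matrices, region summaries, metagene profiles and
matched-pair log2 fold-change matrices.

The scale-regions layout mirrors common metagene practice: fixed-width bins
over an upstream flank, the gene body resampled into a fixed number of
equal-width bins (length-weighted means, so fractional base-pair bin edges
are exact), and fixed-width bins over a downstream flank. Minus-strand genes
are orientation-flipped so column 0 is always the 5'-most position.

Fold changes are computed cellwise as log2((null + d) / (WT + d)) with a
positive pseudocount d, which keeps zero-coverage bins finite and bounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import CoverageTrack, GenomeAnnotation, RegionLayout, ValidationError
from .universe import GeneUniverse


@dataclass
class OccupancyMatrix:
    """genes x bins mean normalized coverage for one sample and modality."""

    sample_id: str
    modality: str
    values: pd.DataFrame  # index: universe gene order; columns: bin index
    layout: RegionLayout
    log_transformed: bool = False

    def log2(self) -> "OccupancyMatrix":
        """log2(x + pseudocount) display transform."""
        if self.log_transformed:
            raise ValidationError("matrix already log-transformed")
        out = np.log2(self.values + self.layout.pseudocount)
        return OccupancyMatrix(self.sample_id, self.modality, out, self.layout, True)


@dataclass
class FoldChangeMatrix:
    """genes x bins log2((null + d)/(WT + d)) for one matched pair and modality."""

    pair_id: str
    modality: str
    values: pd.DataFrame
    layout: RegionLayout


def _gene_bin_edges(gene, layout: RegionLayout) -> np.ndarray:
    """Strand-oriented bin edges for one gene (5' -> 3'), fractional bp allowed."""
    up = np.arange(layout.flank_bins + 1) * layout.flank_bin  # 0 .. flank
    body = np.linspace(0, gene.length, layout.body_bins + 1)
    down = up
    if gene.strand == "+":
        edges = np.concatenate(
            [gene.start - layout.flank + up, gene.start + body[1:], gene.end + down[1:]]
        )
    else:
        # build in genomic coordinates 3'->5' then reverse to 5'->3' orientation
        edges = np.concatenate(
            [gene.end + layout.flank - up, gene.end - body[1:], gene.start - down[1:]]
        )
    return edges


def build_scaled_matrix(
    track: CoverageTrack,
    universe: GeneUniverse,
    annotation: GenomeAnnotation,
    layout: RegionLayout = RegionLayout(),
    modality: str = "",
) -> OccupancyMatrix:
    """Compute the scale-regions matrix of one normalized track.

    Rows follow the universe order; minus-strand genes are flipped so the
    first column is the 5'-most bin. Body bins use exact length-weighted
    means over fractional bin edges.
    """
    if universe.n == 0:
        raise ValidationError("empty gene universe")
    genes = annotation.by_id()
    rows = np.empty((universe.n, layout.n_bins), dtype=np.float64)
    for r, gid in enumerate(universe.gene_ids):
        gene = genes[gid]
        edges = _gene_bin_edges(gene, layout)
        if gene.strand == "+":
            rows[r] = track.binned_means(gene.chrom, edges)
        else:
            # edges descend in genomic coordinates; integrate on the reverse
            rows[r] = track.binned_means(gene.chrom, edges[::-1])[::-1]
    df = pd.DataFrame(rows, index=list(universe.gene_ids))
    return OccupancyMatrix(track.sample_id, modality, df, layout)


def pairwise_log2fc(
    null_matrix: OccupancyMatrix, wt_matrix: OccupancyMatrix, pair_id: str = ""
) -> FoldChangeMatrix:
    """Cellwise log2((null + d)/(WT + d)); inputs must be linear scale."""
    if null_matrix.log_transformed or wt_matrix.log_transformed:
        raise ValidationError("fold changes require linear-scale (pre-transform) matrices")
    if null_matrix.values.shape != wt_matrix.values.shape or not null_matrix.values.index.equals(
        wt_matrix.values.index
    ):
        raise ValidationError("fold-change inputs must share universe and layout")
    if null_matrix.layout != wt_matrix.layout:
        raise ValidationError("fold-change inputs must share the same layout")
    d = null_matrix.layout.pseudocount
    fc = np.log2((null_matrix.values + d) / (wt_matrix.values + d))
    return FoldChangeMatrix(
        pair_id=pair_id, modality=null_matrix.modality, values=fc, layout=null_matrix.layout
    )


REGIONS = ("upstream", "tss", "body", "tes", "downstream")


def summarize_regions(
    track: CoverageTrack,
    universe: GeneUniverse,
    annotation: GenomeAnnotation,
    layout: RegionLayout = RegionLayout(),
) -> pd.DataFrame:
    """Per-gene mean coverage in five strand-oriented windows.

    tss = [TSS - h, TSS + h); body = [TSS + h, TES - h'); tes = [TES - h',
    TES + h'); upstream/downstream = the flank windows outside the gene
    (oriented by strand). Requires the body window to be non-empty, which the
    > 2 kb length filter guarantees at the default half-widths.
    """
    genes = annotation.by_id()
    rows = []
    for gid in universe.gene_ids:
        g = genes[gid]
        h, h2 = layout.tss_halfwidth, layout.tes_halfwidth
        if g.length <= h + h2:
            raise ValidationError(f"gene {gid}: TSS/TES windows collide (empty body window)")
        if g.strand == "+":
            windows = {
                "upstream": (g.start - layout.flank, g.start),
                "tss": (g.start - h, g.start + h),
                "body": (g.start + h, g.end - h2),
                "tes": (g.end - h2, g.end + h2),
                "downstream": (g.end, g.end + layout.flank),
            }
        else:
            windows = {
                "upstream": (g.end, g.end + layout.flank),
                "tss": (g.end - h, g.end + h),
                "body": (g.start + h2, g.end - h),
                "tes": (g.start - h2, g.start + h2),
                "downstream": (g.start - layout.flank, g.start),
            }
        rows.append({"gene_id": gid, **{k: track.window_mean(g.chrom, *w) for k, w in windows.items()}})
    return pd.DataFrame(rows).set_index("gene_id")


def metagene_profile(
    matrix, gene_ids: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, int]:
    """Column means of an occupancy or fold-change matrix, optionally
    restricted to a gene subset; returns (profile, n_genes)."""
    values = matrix.values
    if gene_ids is not None:
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(values.index)
        if missing:
            raise ValidationError(f"genes not in matrix: {sorted(missing)[:5]}")
        values = values.loc[gene_ids]
    if len(values) == 0:
        raise ValidationError("empty gene selection for metagene profile")
    return values.mean(axis=0).to_numpy(), len(values)
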