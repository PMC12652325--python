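"""Analysis gene universe: polymerase-occupied genes passing length and
neighbor-gap filters.

A gene enters the universe iff it is (i) RNA pol II occupied in wild-type
samples, (ii) strictly longer than 2 kb, and (iii) at least 2 kb away from
the nearest other gene span on the same chromosome (strand-ignored;
overlapping genes count as gap 0). The length filter is strict (> 2000 bp)
while the gap filter is inclusive (>= 2000 bp).

Occupancy can be decided from peak calls (a peak overlapping the promoter
window in a quorum of replicates) or directly from wild-type polymerase
coverage (promoter-window mean above a multiple of the genome-wide median
non-zero coverage). Both the window and the quorum are configuration, not
biology fixed by the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import CoverageTrack, GenomeAnnotation, ValidationError

MIN_GENE_LENGTH = 2000  # strict: length must exceed this
MIN_NEIGHBOR_GAP = 2000  # inclusive: gap of exactly 2000 passes


@dataclass
class GeneUniverse:
    """Retained gene list plus per-gene filter outcomes."""

    gene_ids: List[str]
    outcomes: pd.DataFrame = field(repr=False)  # index gene_id; occupied, length_ok, gap_ok, retained

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return self.outcomes.copy()


def _tss_window(gene, halfwidth: int) -> tuple:
    tss = gene.tss
    return tss - halfwidth, tss + halfwidth


def detect_occupied_genes(
    annotation: GenomeAnnotation,
    mode: str = "threshold",
    tracks: Optional[Sequence[CoverageTrack]] = None,
    peak_sets: Optional[Sequence[Dict[str, np.ndarray]]] = None,
    window_halfwidth: int = 1000,
    threshold_multiple: float = 2.0,
    quorum: Optional[int] = None,
) -> Set[str]:
    """Return the gene ids considered RNA pol II occupied.

    ``peaks`` mode: a gene is occupied in one replicate iff any peak overlaps
    the strand-oriented promoter window [TSS - w, TSS + w); occupied overall
    iff that holds in >= quorum replicates (default: majority).

    ``threshold`` mode: occupied in one replicate iff the mean normalized
    coverage in that window is >= threshold_multiple x the genome-wide median
    non-zero coverage of the replicate's track.
    """
    if mode == "peaks":
        if not peak_sets:
            raise ValidationError("peaks mode requires at least one peak set")
        n_rep = len(peak_sets)
        votes = np.zeros(len(annotation.genes), dtype=np.int64)
        for peaks in peak_sets:
            if not peaks or all(arr.size == 0 for arr in peaks.values()):
                warnings.warn("empty peak file: replicate contributes zero occupied genes")
            trees = {c: IntervalTree.from_tuples(map(tuple, arr)) for c, arr in peaks.items() if arr.size}
            for i, gene in enumerate(annotation.genes):
                lo, hi = _tss_window(gene, window_halfwidth)
                tree = trees.get(gene.chrom)
                if tree is not None and tree.overlap(lo, hi):
                    votes[i] += 1
    elif mode == "threshold":
        if not tracks:
            raise ValidationError("threshold mode requires at least one WT polymerase track")
        n_rep = len(tracks)
        votes = np.zeros(len(annotation.genes), dtype=np.int64)
        by_chrom: Dict[str, List[int]] = {}
        for i, gene in enumerate(annotation.genes):
            by_chrom.setdefault(gene.chrom, []).append(i)
        for track in tracks:
            cutoff = threshold_multiple * track.median_nonzero_coverage()
            for chrom, idxs in by_chrom.items():
                lo = np.array([annotation.genes[i].tss - window_halfwidth for i in idxs], dtype=float)
                hi = lo + 2 * window_halfwidth
                f_lo = track.window_integrals(chrom, lo)
                f_hi = track.window_integrals(chrom, hi)
                means = (f_hi - f_lo) / (2 * window_halfwidth)
                ok = (means >= cutoff) & (means > 0)
                votes[np.array(idxs)[ok]] += 1
    else:
        raise ValidationError(f"unknown occupancy mode {mode!r} (expected 'peaks' or 'threshold')")

    if quorum is None:
        quorum = n_rep // 2 + 1
    return {g.gene_id for g, v in zip(annotation.genes, votes) if v >= quorum}


def neighbor_gaps(annotation: GenomeAnnotation) -> pd.Series:
    """Distance from each gene span to the nearest other gene span on the
    same chromosome (either side, strand-ignored); overlap counts as 0;
    genes alone on their chromosome get +inf.

    Sort-based O(n log n); validated against a brute-force all-pairs oracle.
    """
    gaps = pd.Series(np.inf, index=[g.gene_id for g in annotation.genes], dtype=float)
    by_chrom: Dict[str, List] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        if len(genes) < 2:
            continue
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        order = np.argsort(starts, kind="stable")
        s, e = starts[order], ends[order]
        n = len(genes)
        # prefix max of ends excluding self, from the left
        left_max_end = np.full(n, -np.inf)
        running = -np.inf
        for i in range(n):
            left_max_end[i] = running
            running = max(running, e[i])
        # suffix min of starts excluding self, from the right
        right_min_start = np.full(n, np.inf)
        running = np.inf
        for i in range(n - 1, -1, -1):
            right_min_start[i] = running
            running = min(running, s[i])
        # a gene overlaps some other gene iff a previous-start gene ends past
        # its start, or the next start begins before its end
        for rank, idx in enumerate(order):
            g = genes[idx]
            left_gap = g.start - left_max_end[rank]  # may be negative (overlap)
            right_gap = right_min_start[rank] - g.end
            gap = min(left_gap, right_gap)
            gaps.iloc[gaps.index.get_loc(genes[idx].gene_id)] = max(gap, 0.0)
    return gaps


def filter_gene_universe(annotation: GenomeAnnotation, occupied: Set[str]) -> GeneUniverse:
    """Apply the occupancy, length and neighbor-gap filters.

    Retains a gene iff occupied AND length > 2000 bp AND nearest other gene
    span >= 2000 bp away. Records all three outcomes for every gene.
    """
    gaps = neighbor_gaps(annotation)
    rows = []
    for g in annotation.genes:
        occ = g.gene_id in occupied
        length_ok = g.length > MIN_GENE_LENGTH
        gap_ok = gaps[g.gene_id] >= MIN_NEIGHBOR_GAP
        rows.append(
            {
                "gene_id": g.gene_id,
                "occupied": occ,
                "length_ok": length_ok,
                "gap_ok": gap_ok,
                "retained": occ and length_ok and gap_ok,
            }
        )
    outcomes = pd.DataFrame(rows).set_index("gene_id")
    retained = [g.gene_id for g in annotation.genes if outcomes.loc[g.gene_id, "retained"]]
    return GeneUniverse(gene_ids=retained, outcomes=outcomes)
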