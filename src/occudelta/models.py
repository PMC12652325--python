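"""Core domain types: gene models, annotations, run-length coverage tracks,
sample metadata, expression tables and the scale-regions layout.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
the package; GTF input is converted on read. A :class:`CoverageTrack` stores,
for each chromosome, a full partition of ``[0, size)`` into runs of constant
coverage, which makes window means exact (no binning approximation) and makes
bedGraph round-trips lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")
VALID_NAMESPACES = ("target", "spikein")
VALID_GENOTYPES = ("WT", "null")
VALID_MODALITIES = ("AFF4", "polII", "pS2polII", "RNA")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene span on one chromosome.

    ``start``/``end`` are 0-based half-open. The transcription start site
    (TSS) is ``start`` on the + strand and ``end`` on the - strand; the
    transcription end site (TES) is the opposite anchor.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """A set of gene models plus chromosome sizes for one genome namespace."""

    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    namespace: str = "target"

    def __post_init__(self) -> None:
        if self.namespace not in VALID_NAMESPACES:
            raise ValidationError(f"namespace must be one of {VALID_NAMESPACES}")
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValidationError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in chrom_sizes")
            if g.start < 0 or g.end > self.chrom_sizes[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id}: [{g.start}, {g.end}) outside chromosome "
                    f"{g.chrom} of length {self.chrom_sizes[g.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]


def _canonicalize_runs(edges: np.ndarray, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge adjacent runs with equal value; drop zero-width runs."""
    widths = np.diff(edges)
    keep = widths > 0
    edges_kept = np.concatenate([edges[:-1][keep], edges[-1:]])
    vals = values[keep]
    if len(vals) == 0:
        return edges_kept, vals
    change = np.concatenate([[True], vals[1:] != vals[:-1]])
    new_edges = np.concatenate([edges_kept[:-1][change], edges_kept[-1:]])
    return new_edges, vals[change]


@dataclass
class CoverageTrack:
    """Run-length coverage for one sample over one genome namespace.

    ``data`` maps chromosome name to ``(edges, values)`` where ``edges`` is a
    strictly increasing int64 array starting at 0 and ending at the chromosome
    size, and ``values`` (length ``len(edges) - 1``) holds the constant
    coverage of each run. Gaps are represented as explicit zero-valued runs,
    so the runs always partition the chromosome.
    """

    sample_id: str
    namespace: str
    chrom_sizes: Dict[str, int]
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    total_fragments: Optional[int] = None

    def __post_init__(self) -> None:
        if self.namespace not in VALID_NAMESPACES:
            raise ValidationError(f"namespace must be one of {VALID_NAMESPACES}")
        for chrom, size in self.chrom_sizes.items():
            if chrom not in self.data:
                self.data[chrom] = (
                    np.array([0, size], dtype=np.int64),
                    np.zeros(1, dtype=np.float64),
                )
        for chrom, (edges, values) in self.data.items():
            if chrom not in self.chrom_sizes:
                raise ValidationError(f"track chromosome {chrom!r} not in chrom_sizes")
            if edges[0] != 0 or edges[-1] != self.chrom_sizes[chrom]:
                raise ValidationError(f"runs on {chrom} must partition [0, {self.chrom_sizes[chrom]})")
            if np.any(np.diff(edges) <= 0):
                raise ValidationError(f"run edges on {chrom} must be strictly increasing")
            if len(values) != len(edges) - 1:
                raise ValidationError(f"edge/value length mismatch on {chrom}")
            if np.any(values < 0):
                raise ValidationError(f"negative coverage value on {chrom}")

    # ---- construction -------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        sample_id: str,
        namespace: str,
        chrom_sizes: Dict[str, int],
        intervals: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_fragments: Optional[int] = None,
    ) -> "CoverageTrack":
        """Build a track from additive deposit intervals per chromosome.

        ``intervals[chrom] = (starts, ends, values)``; overlapping deposits
        add. Intervals are clipped to chromosome bounds.
        """
        data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, vals) in intervals.items():
            size = chrom_sizes[chrom]
            starts = np.clip(np.asarray(starts, dtype=np.int64), 0, size)
            ends = np.clip(np.asarray(ends, dtype=np.int64), 0, size)
            vals = np.asarray(vals, dtype=np.float64)
            if np.any(vals < 0):
                raise ValidationError("deposit intervals must have non-negative values")
            ok = ends > starts
            starts, ends, vals = starts[ok], ends[ok], vals[ok]
            bounds = np.concatenate([[0], starts, ends, [size]])
            edges = np.unique(bounds)
            delta = np.zeros(len(edges), dtype=np.float64)
            si = np.searchsorted(edges, starts)
            ei = np.searchsorted(edges, ends)
            np.add.at(delta, si, vals)
            np.add.at(delta, ei, -vals)
            values = np.cumsum(delta)[:-1]
            # all deposits are non-negative, so negatives are cancellation residue
            values = np.where(values < 1e-9, 0.0, values)
            edges, values = _canonicalize_runs(edges, values)
            data[chrom] = (edges, values)
        return cls(
            sample_id=sample_id,
            namespace=namespace,
            chrom_sizes=dict(chrom_sizes),
            data=data,
            total_fragments=total_fragments,
        )

    # ---- queries ------------------------------------------------------

    def area(self, chrom: Optional[str] = None) -> float:
        """Total coverage * width, over one chromosome or the whole track."""
        chroms = [chrom] if chrom is not None else list(self.data)
        total = 0.0
        for c in chroms:
            edges, values = self.data[c]
            total += float(np.dot(values, np.diff(edges)))
        return total

    def _prefix_area(self, chrom: str) -> np.ndarray:
        # cached: run data is treated as immutable after construction
        cache = self.__dict__.setdefault("_prefix_cache", {})
        if chrom not in cache:
            edges, values = self.data[chrom]
            cache[chrom] = np.concatenate([[0.0], np.cumsum(values * np.diff(edges))])
        return cache[chrom]

    def window_integrals(self, chrom: str, bounds: np.ndarray) -> np.ndarray:
        """Exact coverage integrals between consecutive positions in ``bounds``.

        ``bounds`` may be any array of positions (clipped to chromosome);
        returns ``F(bounds) `` evaluated at each position, where F is the
        cumulative coverage area from 0.
        """
        edges, values = self.data[chrom]
        prefix = self._prefix_area(chrom)
        pos = np.clip(np.asarray(bounds, dtype=np.float64), 0, self.chrom_sizes[chrom])
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(values) - 1)
        return prefix[idx] + values[idx] * (pos - edges[idx])

    def window_mean(self, chrom: str, start: float, end: float) -> float:
        """Mean coverage over [start, end), clipped to the chromosome."""
        if end <= start:
            raise ValidationError(f"empty window [{start}, {end})")
        f = self.window_integrals(chrom, np.array([start, end]))
        lo = max(start, 0)
        hi = min(end, self.chrom_sizes[chrom])
        width = hi - lo
        if width <= 0:
            return 0.0
        return float((f[1] - f[0]) / (end - start))

    def binned_means(self, chrom: str, bin_edges: np.ndarray) -> np.ndarray:
        """Mean coverage in each bin of a (possibly fractional) edge array.

        Positions outside the chromosome contribute zero coverage but full
        width (flanks of genes near chromosome ends are zero-padded).
        """
        f = self.window_integrals(chrom, bin_edges)
        widths = np.diff(np.asarray(bin_edges, dtype=np.float64))
        if np.any(widths <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        return np.diff(f) / widths

    def median_nonzero_coverage(self) -> float:
        """Width-weighted median of strictly positive coverage values."""
        vals: List[np.ndarray] = []
        widths: List[np.ndarray] = []
        for edges, values in self.data.values():
            w = np.diff(edges)
            nz = values > 0
            vals.append(values[nz])
            widths.append(w[nz])
        v = np.concatenate(vals) if vals else np.array([])
        if v.size == 0:
            return 0.0
        w = np.concatenate(widths).astype(np.float64)
        order = np.argsort(v, kind="stable")
        v, w = v[order], w[order]
        cum = np.cumsum(w)
        return float(v[np.searchsorted(cum, cum[-1] / 2.0)])

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor <= 0:
            raise ValidationError(f"scale factor must be positive, got {factor}")
        data = {c: (e.copy(), v * factor) for c, (e, v) in self.data.items()}
        return replace(self, data=data)

    def nonzero_intervals(self) -> Iterator[Tuple[str, int, int, float]]:
        """Yield (chrom, start, end, value) for runs with value != 0."""
        for chrom in sorted(self.data):
            edges, values = self.data[chrom]
            for i in range(len(values)):
                if values[i] != 0:
                    yield chrom, int(edges[i]), int(edges[i + 1]), float(values[i])

    def equal(self, other: "CoverageTrack") -> bool:
        if set(self.data) != set(other.data):
            return False
        for chrom in self.data:
            e1, v1 = self.data[chrom]
            e2, v2 = other.data[chrom]
            if len(e1) != len(e2) or not np.array_equal(e1, e2) or not np.array_equal(v1, v2):
                return False
        return True


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing sample: genotype, assay modality and matched pair."""

    sample_id: str
    genotype: str
    modality: str
    pair_id: str = ""
    target_path: str = ""
    spikein_path: str = ""
    target_fragments: Optional[int] = None
    spikein_fragments: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype not in VALID_GENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id}: genotype must be one of {VALID_GENOTYPES}, got {self.genotype!r}"
            )
        if self.modality not in VALID_MODALITIES:
            raise ValidationError(
                f"sample {self.sample_id}: unknown modality {self.modality!r} (expected one of {VALID_MODALITIES})"
            )
        if self.modality == "RNA" and self.spikein_path:
            raise ValidationError(f"sample {self.sample_id}: RNA samples carry no spike-in path")


def validate_pairing(samples: List[SampleMetadata]) -> None:
    """Check that each (pair_id, modality) has exactly one WT and one null.

    RNA samples are exempt: they are replicate-matched by genotype only.
    """
    groups: Dict[Tuple[str, str], List[SampleMetadata]] = {}
    for s in samples:
        if s.modality == "RNA":
            continue
        groups.setdefault((s.pair_id, s.modality), []).append(s)
    for (pair_id, modality), members in groups.items():
        genos = sorted(m.genotype for m in members)
        if genos != ["WT", "null"]:
            raise ValidationError(
                f"pair {pair_id!r} / modality {modality}: expected exactly one WT and one "
                f"null sample, got genotypes {genos}"
            )


@dataclass
class ExpressionTable:
    """Gene-level RNA-seq counts with reads-per-million normalization."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    genotypes: Dict[str, str]  # sample -> WT | null

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("expression counts must be non-negative")
        missing = set(self.counts.columns) - set(self.genotypes)
        if missing:
            raise ValidationError(f"samples missing genotype labels: {sorted(missing)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def rpm(self) -> pd.DataFrame:
        """Reads per million: counts scaled so each column sums to 1e6."""
        libs = self.library_sizes.replace(0, np.nan)
        return self.counts / libs * 1e6

    def samples_of(self, genotype: str) -> List[str]:
        return [s for s in self.counts.columns if self.genotypes[s] == genotype]


@dataclass(frozen=True)
class RegionLayout:
    """Geometry of the scale-regions matrix and of region summaries.

    Flanks are binned at fixed width; the gene body is resampled into exactly
    ``body_bins`` equal-width bins regardless of gene length. TSS/TES summary
    windows are half-open windows of ``2 * tss_halfwidth`` (``tes_halfwidth``)
    centred on the anchors; the body summary window excludes both.
    """

    flank: int = 2000
    flank_bin: int = 50
    body_bins: int = 100
    tss_halfwidth: int = 250
    tes_halfwidth: int = 250
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("flank", "flank_bin", "body_bins", "tss_halfwidth", "tes_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"layout field {name} must be positive")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.flank % self.flank_bin != 0:
            raise ValidationError("flank must be divisible by flank_bin")

    @property
    def flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins
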