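"""Readers and writers for the plain-text formats the pipeline touches:
BED6/BED12 and minimal GTF gene annotations, bedGraph coverage, BED3 peaks,
TSV sample sheets and gene-count tables.

bedGraph semantics: the file stores only the runs it mentions; gaps are
implicitly zero. On read the runs are validated (sorted after sorting,
non-overlapping, inside chromosome bounds, non-negative values) and padded
with explicit zero runs so the in-memory track partitions each chromosome.
Writing emits only non-zero runs with ``repr`` float formatting, which makes
the write/read round trip lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .models import (
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    GenomeAnnotation,
    SampleMetadata,
    ValidationError,
    validate_pairing,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: Dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: PathLike) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: PathLike,
    chrom_sizes: Dict[str, int],
    fmt: str = "BED",
    namespace: str = "target",
) -> GenomeAnnotation:
    """Read a gene annotation from BED6/BED12 or minimal GTF (gene lines).

    GTF coordinates (1-based, end-inclusive) are converted to 0-based
    half-open on read. Duplicate gene identifiers are rejected.
    """
    if fmt.upper().startswith("BED"):
        genes = _read_bed_genes(path)
    elif fmt.upper() == "GTF":
        genes = _read_gtf_genes(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected BED or GTF)")
    return GenomeAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes), namespace=namespace)


def _read_bed_genes(path: PathLike) -> List[GeneModel]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: BED gene records need >= 6 columns")
        try:
            chrom, start, end, name, _score, strand = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            genes.append(GeneModel(gene_id=name, chrom=chrom, start=start, end=end, strand=strand))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gtf_genes(path: PathLike) -> List[GeneModel]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ParseError(f"{path}:{lineno}: GTF records need 9 tab-separated columns")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
        if feature != "gene":
            continue
        gene_id = None
        for token in attrs.rstrip(";").split(";"):
            token = token.strip()
            if token.startswith("gene_id"):
                gene_id = token.split(None, 1)[1].strip().strip('"')
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: gene record without gene_id attribute")
        try:
            genes.append(
                GeneModel(gene_id=gene_id, chrom=chrom, start=int(start) - 1, end=int(end), strand=strand)
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_annotation(annotation: GenomeAnnotation, path: PathLike) -> None:
    """Write genes as BED6 (name = gene_id, score = 0)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: PathLike,
    chrom_sizes: Dict[str, int],
    namespace: str = "target",
    sample_id: str = "",
    total_fragments: Optional[int] = None,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a run-length :class:`CoverageTrack`.

    Input runs may be unsorted but must not overlap; gaps become explicit
    zero runs; negative values and runs outside chromosome bounds are errors.
    """
    recs: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = parts[0]
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: interval end ({end}) must exceed start ({start})")
        if value < 0:
            raise ValidationError(f"{path}:{lineno}: negative coverage value {value}")
        if chrom not in chrom_sizes:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or end > chrom_sizes[chrom]:
            raise ValidationError(
                f"{path}:{lineno}: interval [{start}, {end}) outside chromosome {chrom} "
                f"of length {chrom_sizes[chrom]}"
            )
        recs.setdefault(chrom, []).append((start, end, value))

    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, rows in recs.items():
        rows.sort()
        size = chrom_sizes[chrom]
        edges = [0]
        values = []
        for start, end, value in rows:
            if start < edges[-1]:
                raise ValidationError(f"{path}: overlapping bedGraph intervals on {chrom} at {start}")
            if start > edges[-1]:
                edges.append(start)
                values.append(0.0)
            edges.append(end)
            values.append(value)
        if edges[-1] < size:
            edges.append(size)
            values.append(0.0)
        data[chrom] = (np.array(edges, dtype=np.int64), np.array(values, dtype=np.float64))

    track = CoverageTrack(
        sample_id=sample_id or Path(path).stem,
        namespace=namespace,
        chrom_sizes=dict(chrom_sizes),
        data=data,
        total_fragments=total_fragments,
    )
    # canonicalize: merge adjacent equal runs so round trips are stable
    from .models import _canonicalize_runs

    track.data = {c: _canonicalize_runs(e, v) for c, (e, v) in track.data.items()}
    return track


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write non-zero runs as bedGraph with round-trippable float formatting."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.nonzero_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def read_peaks(path: PathLike) -> Dict[str, np.ndarray]:
    """Read BED3+ peak calls; returns chrom -> array of (start, end) sorted by start."""
    peaks: Dict[str, List[Tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED peaks need >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: peak end must exceed start")
        peaks.setdefault(parts[0], []).append((start, end))
    return {c: np.array(sorted(p), dtype=np.int64).reshape(-1, 2) for c, p in peaks.items()}


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "genotype", "modality", "pair_id"]


def read_sample_sheet(path: PathLike) -> List[SampleMetadata]:
    """Read the TSV sample sheet and validate WT/null pairing per modality.

    Required columns: sample_id, genotype, modality, pair_id. Optional:
    target_path, spikein_path, target_fragments, spikein_fragments. RNA rows
    need no pair_id or spike-in.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                genotype=row["genotype"],
                modality=row["modality"],
                pair_id=row.get("pair_id", ""),
                target_path=row.get("target_path", ""),
                spikein_path=row.get("spikein_path", ""),
                target_fragments=int(row["target_fragments"]) if row.get("target_fragments") else None,
                spikein_fragments=int(row["spikein_fragments"]) if row.get("spikein_fragments") else None,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id in sample sheet")
    validate_pairing(samples)
    return samples


def write_sample_sheet(samples: List[SampleMetadata], path: PathLike) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "modality": s.modality,
                "pair_id": s.pair_id,
                "target_path": s.target_path,
                "spikein_path": s.spikein_path,
                "target_fragments": "" if s.target_fragments is None else s.target_fragments,
                "spikein_fragments": "" if s.spikein_fragments is None else s.spikein_fragments,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def read_expression_table(path: PathLike, genotypes: Dict[str, str]) -> ExpressionTable:
    """Gene-count TSV: first column gene_id, remaining columns sample counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.issubdtype(df.values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric values in count table")
    if np.any(df.values < 0) or np.any(df.values != np.round(df.values)):
        raise ValidationError(f"{path}: counts must be non-negative integers")
    return ExpressionTable(counts=df.astype(np.int64), genotypes=dict(genotypes))


def write_expression_table(table: ExpressionTable, path: PathLike) -> None:
    out = table.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
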