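"""End-to-end pipeline: spike-in normalization -> gene universe ->
scale-regions matrices and fold changes -> pair selection -> clustering ->
median-of-ratios correlations -> cluster expression comparison.

Stages communicate through TSV files in the output directory, so each stage
can be run (and tested) independently from the CLI; every output carries the
configuration hash and seed in a leading comment line, and a rerun with the
same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as odio
from .cluster import (
    build_cluster_features,
    cluster_genes,
    compare_cluster_expression,
    correlation_table,
    fraction_decreased,
    label_clusters,
    median_ratio_per_gene,
    rna_expression_ratios,
    select_pairs,
    spearman_by_cluster,
)
from .models import RegionLayout, ValidationError
from .occupancy import build_scaled_matrix, pairwise_log2fc, summarize_regions
from .spikenorm import SpikeInStats, compute_scale_factors, count_spikein_fragments, factors_table, normalize_track
from .universe import GeneUniverse, detect_occupied_genes, filter_gene_universe

logger = logging.getLogger("occudelta")

CHIP_MODALITIES = ("AFF4", "polII", "pS2polII")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    annotation: str
    chrom_sizes: str
    sample_sheet: str
    outdir: str
    counts: Optional[str] = None
    spike_chrom_sizes: Optional[str] = None
    peaks: Tuple[str, ...] = ()
    annotation_format: str = "BED"
    normalization: str = "min"
    fragment_length: int = 200
    occupied_mode: str = "threshold"  # threshold | peaks
    occupied_window: int = 1000
    occupied_threshold: float = 2.0
    occupied_quorum: Optional[int] = None
    layout: RegionLayout = field(default_factory=RegionLayout)
    ratio_pseudocount: float = 1.0
    n_select: int = 2
    k: int = 3
    linkage: str = "ward"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        layout = RegionLayout(**raw.pop("layout", {}))
        if "peaks" in raw:
            raw["peaks"] = tuple(raw["peaks"])
        base = Path(path).resolve().parent
        cfg = cls(layout=layout, **raw)
        # resolve input paths relative to the config file
        for name in ("annotation", "chrom_sizes", "sample_sheet", "counts", "spike_chrom_sizes", "outdir"):
            val = getattr(cfg, name)
            if val and not Path(val).is_absolute():
                setattr(cfg, name, str(base / val))
        if cfg.peaks:
            cfg.peaks = tuple(str(base / p) if not Path(p).is_absolute() else p for p in cfg.peaks)
        return cfg

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout)
        d.pop("outdir", None)  # analysis parameters only; not the destination
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for name in ("annotation", "chrom_sizes", "sample_sheet"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError(f"startup: missing {name} file {p!r}")
        if self.counts and not Path(self.counts).exists():
            raise PipelineError(f"startup: missing counts file {self.counts!r}")
        for p in self.peaks:
            if not Path(p).exists():
                raise PipelineError(f"startup: missing peaks file {p!r}")


def _header(config: PipelineConfig) -> str:
    return f"# occudelta config_hash={config.hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def _read_stage_tsv(path: Path, **kwargs) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(f"missing upstream output {path}; run the earlier stage first")
    # keep_default_na=False: the genotype literal "null" must not parse as NaN
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[""], **kwargs)


def _load_samples(config: PipelineConfig):
    samples = odio.read_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).resolve().parent
    return samples, base


def _chip_samples(samples):
    return [s for s in samples if s.modality != "RNA"]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_normalize(config: PipelineConfig) -> pd.DataFrame:
    """Per-modality spike-in scale factors -> factors.tsv."""
    t0 = time.time()
    samples, base = _load_samples(config)
    spike_sizes = odio.read_chrom_sizes(config.spike_chrom_sizes) if config.spike_chrom_sizes else {}
    rows = []
    for modality in CHIP_MODALITIES:
        group = [s for s in samples if s.modality == modality]
        if not group:
            continue
        stats = []
        for s in sorted(group, key=lambda s: s.sample_id):
            if s.spikein_fragments is not None:
                n_spike = s.spikein_fragments
            else:
                if not s.spikein_path:
                    raise PipelineError(f"normalize: sample {s.sample_id} has no spike-in count or path")
                track = odio.read_bedgraph(
                    base / s.spikein_path, spike_sizes, namespace="spikein", sample_id=s.sample_id
                )
                n_spike = count_spikein_fragments(track, config.fragment_length)
            stats.append(
                SpikeInStats(
                    sample_id=s.sample_id,
                    target_fragments=s.target_fragments or 0,
                    spikein_fragments=n_spike,
                )
            )
        stats = compute_scale_factors(stats, convention=config.normalization)
        df = factors_table(stats)
        df.insert(1, "modality", modality)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True).set_index("sample_id")
    _write_tsv(out, Path(config.outdir) / "factors.tsv", config)
    logger.info("normalize: %d samples in %.1fs", len(out), time.time() - t0)
    return out


def _load_factors(config: PipelineConfig) -> pd.Series:
    df = _read_stage_tsv(Path(config.outdir) / "factors.tsv", index_col=0)
    return df["scale_factor"]


def _normalized_track(config: PipelineConfig, sample, chrom_sizes, factors: pd.Series):
    base = Path(config.sample_sheet).resolve().parent
    track = odio.read_bedgraph(
        base / sample.target_path, chrom_sizes, namespace="target", sample_id=sample.sample_id
    )
    return normalize_track(track, float(factors[sample.sample_id]))


def stage_universe(config: PipelineConfig) -> GeneUniverse:
    """Occupancy detection on WT polymerase samples + the two geometry
    filters -> universe.tsv."""
    t0 = time.time()
    chrom_sizes = odio.read_chrom_sizes(config.chrom_sizes)
    annotation = odio.read_gene_annotation(config.annotation, chrom_sizes, fmt=config.annotation_format)
    samples, _ = _load_samples(config)
    if config.occupied_mode == "peaks":
        peak_sets = [odio.read_peaks(p) for p in config.peaks]
        occupied = detect_occupied_genes(
            annotation,
            mode="peaks",
            peak_sets=peak_sets,
            window_halfwidth=config.occupied_window,
            quorum=config.occupied_quorum,
        )
    else:
        factors = _load_factors(config)
        wt_polii = [s for s in samples if s.modality == "polII" and s.genotype == "WT"]
        if not wt_polii:
            raise PipelineError("universe: no WT polII samples for threshold occupancy detection")
        tracks = [_normalized_track(config, s, chrom_sizes, factors) for s in wt_polii]
        occupied = detect_occupied_genes(
            annotation,
            mode="threshold",
            tracks=tracks,
            window_halfwidth=config.occupied_window,
            threshold_multiple=config.occupied_threshold,
            quorum=config.occupied_quorum,
        )
    universe = filter_gene_universe(annotation, occupied)
    _write_tsv(universe.outcomes, Path(config.outdir) / "universe.tsv", config)
    logger.info("universe: %d of %d genes retained in %.1fs", universe.n, len(annotation), time.time() - t0)
    return universe


def _load_universe(config: PipelineConfig, annotation) -> GeneUniverse:
    outcomes = _read_stage_tsv(Path(config.outdir) / "universe.tsv", index_col=0)
    retained = [g.gene_id for g in annotation.genes if bool(outcomes.loc[g.gene_id, "retained"])]
    return GeneUniverse(gene_ids=retained, outcomes=outcomes)


def stage_matrices(config: PipelineConfig) -> None:
    """Normalized scale-regions matrices, per-pair fold-change matrices and
    per-sample region summaries -> matrices/ and region_summaries.tsv."""
    t0 = time.time()
    chrom_sizes = odio.read_chrom_sizes(config.chrom_sizes)
    annotation = odio.read_gene_annotation(config.annotation, chrom_sizes, fmt=config.annotation_format)
    universe = _load_universe(config, annotation)
    samples, _ = _load_samples(config)
    factors = _load_factors(config)
    outdir = Path(config.outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)

    summaries = []
    matrices = {}
    for s in _chip_samples(samples):
        track = _normalized_track(config, s, chrom_sizes, factors)
        matrices[s.sample_id] = build_scaled_matrix(track, universe, annotation, config.layout, s.modality)
        summ = summarize_regions(track, universe, annotation, config.layout)
        summ.insert(0, "sample_id", s.sample_id)
        summ.insert(1, "modality", s.modality)
        summ.insert(2, "pair_id", s.pair_id)
        summ.insert(3, "genotype", s.genotype)
        summaries.append(summ.reset_index())
    _write_tsv(
        pd.concat(summaries, ignore_index=True),
        outdir / "region_summaries.tsv",
        config,
        index=False,
    )

    by_key = {(s.modality, s.pair_id, s.genotype): s.sample_id for s in _chip_samples(samples)}
    pair_ids = sorted({s.pair_id for s in _chip_samples(samples)})
    modalities = sorted({s.modality for s in _chip_samples(samples)})
    for modality in modalities:
        for pair in pair_ids:
            null_m = matrices[by_key[(modality, pair, "null")]]
            wt_m = matrices[by_key[(modality, pair, "WT")]]
            fc = pairwise_log2fc(null_m, wt_m, pair_id=pair)
            _write_tsv(fc.values, outdir / "matrices" / f"fc_{modality}_{pair}.tsv", config)
    logger.info("matrices: %d samples in %.1fs", len(matrices), time.time() - t0)


def _load_region_summaries(config: PipelineConfig) -> pd.DataFrame:
    return _read_stage_tsv(Path(config.outdir) / "region_summaries.tsv")


def _paired_summaries(summaries: pd.DataFrame, modality: str):
    """Split the long summary table into per-pair null/WT region tables."""
    sub = summaries[summaries["modality"] == modality]
    null_s, wt_s = {}, {}
    for (pair, genotype), grp in sub.groupby(["pair_id", "genotype"]):
        tbl = grp.set_index("gene_id")[["upstream", "tss", "body", "tes", "downstream"]]
        (null_s if genotype == "null" else wt_s)[pair] = tbl
    return null_s, wt_s


def stage_cluster(config: PipelineConfig):
    """Pair selection, feature assembly, clustering, canonical labelling
    -> clusters.tsv and selected_pairs.json."""
    from .occupancy import FoldChangeMatrix

    t0 = time.time()
    outdir = Path(config.outdir)
    samples, _ = _load_samples(config)
    chip = _chip_samples(samples)
    pair_ids = sorted({s.pair_id for s in chip})
    modalities = sorted({s.modality for s in chip})

    fcs = []
    for modality in modalities:
        for pair in pair_ids:
            vals = _read_stage_tsv(outdir / "matrices" / f"fc_{modality}_{pair}.tsv", index_col=0)
            fcs.append(FoldChangeMatrix(pair_id=pair, modality=modality, values=vals, layout=config.layout))
    selected = select_pairs(fcs, config.n_select)

    summaries = _load_region_summaries(config)
    ratio_summaries = {}
    for modality in modalities:
        null_s, wt_s = _paired_summaries(summaries, modality)
        for region in ("tss", "body", "tes"):
            ratio_summaries[(modality, region)] = median_ratio_per_gene(
                null_s, wt_s, modality, region, pseudocount=config.ratio_pseudocount
            )
    features = build_cluster_features(ratio_summaries, selected, modalities=modalities)
    assignment = cluster_genes(features, k=config.k, linkage=config.linkage)
    assignment.selected_pairs = tuple(selected)
    if config.k == 3:
        polii_body = np.log2(ratio_summaries[("polII", "body")].ratios[list(selected)].median(axis=1))
        assignment = label_clusters(assignment, polii_body)

    out = features.copy()
    out.insert(0, "cluster", assignment.labels)
    out.index.name = "gene_id"
    _write_tsv(out, outdir / "clusters.tsv", config)
    (outdir / "selected_pairs.json").write_text(
        json.dumps({"selected_pairs": list(selected), "config_hash": config.hash(), "seed": config.seed}, sort_keys=True)
    )
    logger.info("cluster: %s in %.1fs", assignment.sizes(), time.time() - t0)
    return assignment


def stage_correlate(config: PipelineConfig) -> Dict:
    """Median-of-ratios correlations per cluster, fraction decreased and the
    cluster expression comparison -> correlations.tsv, median_ratios.tsv,
    expression_comparison.tsv, summary.json."""
    from .cluster import ClusterAssignment

    t0 = time.time()
    outdir = Path(config.outdir)
    clusters_df = _read_stage_tsv(outdir / "clusters.tsv", index_col=0)
    assignment = ClusterAssignment(
        labels=clusters_df["cluster"], features=clusters_df.drop(columns=["cluster"])
    )
    summaries = _load_region_summaries(config)
    modalities = sorted(summaries["modality"].unique())

    med = {}
    for modality in modalities:
        null_s, wt_s = _paired_summaries(summaries, modality)
        med[modality] = median_ratio_per_gene(
            null_s, wt_s, modality, "body", pseudocount=config.ratio_pseudocount
        )
    ratios_out = pd.DataFrame({f"{m}_body_median_ratio": med[m].median for m in modalities})

    results = []
    if "AFF4" in med and "polII" in med:
        results += spearman_by_cluster(
            med["AFF4"].median, med["polII"].median, assignment, "AFF4", "polII", seed=config.seed
        )
    expression = None
    if config.counts:
        samples, _ = _load_samples(config)
        genotypes = {s.sample_id: s.genotype for s in samples if s.modality == "RNA"}
        expression = odio.read_expression_table(config.counts, genotypes)
        rna_ratio = rna_expression_ratios(expression, pseudocount=config.ratio_pseudocount)
        rna_ratio = rna_ratio.loc[assignment.labels.index]
        ratios_out["RNA_median_ratio"] = rna_ratio
        if "AFF4" in med:
            results += spearman_by_cluster(
                med["AFF4"].median, rna_ratio, assignment, "AFF4", "RNA", seed=config.seed
            )

    corr = correlation_table(results) if results else pd.DataFrame()
    _write_tsv(corr, outdir / "correlations.tsv", config)
    ratios_out.index.name = "gene_id"
    _write_tsv(ratios_out, outdir / "median_ratios.tsv", config)

    summary = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "universe_n": int(len(assignment.labels)),
        "cluster_sizes": {k: int(v) for k, v in sorted(assignment.sizes().items())},
        "correlations": [dataclasses.asdict(r) for r in results],
    }
    if "polII" in med:
        summary["fraction_polII_body_decreased"] = fraction_decreased(med["polII"].median)
    if expression is not None:
        comp = compare_cluster_expression(expression, assignment, pseudocount=config.ratio_pseudocount)
        _write_tsv(comp, outdir / "expression_comparison.tsv", config)
        summary["expression_comparison"] = json.loads(comp.to_json(orient="index"))
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    logger.info("correlate: done in %.1fs", time.time() - t0)
    return summary


STAGES = ("normalize", "universe", "matrices", "cluster", "correlate")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages in order; any stage error aborts with its name."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s %(message)s")
    config.validate()
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    funcs = {
        "normalize": stage_normalize,
        "universe": stage_universe,
        "matrices": stage_matrices,
        "cluster": stage_cluster,
        "correlate": stage_correlate,
    }
    result = None
    for stage in STAGES:
        try:
            result = funcs[stage](config)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
            raise PipelineError(f"{stage}: {exc}") from exc
    return result
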