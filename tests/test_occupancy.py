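"""Scale-regions matrices, fold changes, region summaries, metagene profiles
— all validated against an independent per-base brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import occudelta as od
from occudelta.models import ValidationError

from conftest import make_track


def universe_of(ann):
    return od.GeneUniverse(gene_ids=[g.gene_id for g in ann.genes], outcomes=None)


def dense_coverage(track, chrom):
    """Per-base expansion of a run-length track (oracle representation)."""
    size = track.chrom_sizes[chrom]
    dense = np.zeros(size)
    for c, s, e, v in track.nonzero_intervals():
        if c == chrom:
            dense[s:e] = v
    return dense


def brute_force_row(dense, gene, layout):
    """Per-base oracle for one gene's scale-regions row, 5'->3' oriented."""
    def mean_over(a, b):
        # fractional-bp window mean with zero outside the chromosome
        lo, hi = max(a, 0.0), min(b, len(dense))
        if hi <= lo:
            return 0.0
        full = np.arange(int(np.floor(lo)), int(np.ceil(hi)))
        w = np.minimum(full + 1, hi) - np.maximum(full, lo)
        return float((dense[full] * w).sum() / (b - a))

    up_edges = [gene.start - layout.flank + i * layout.flank_bin for i in range(layout.flank_bins + 1)]
    body_edges = list(np.linspace(gene.start, gene.end, layout.body_bins + 1))
    down_edges = [gene.end + i * layout.flank_bin for i in range(layout.flank_bins + 1)]
    if gene.strand == "-":
        up_edges = [gene.end + layout.flank - i * layout.flank_bin for i in range(layout.flank_bins + 1)]
        body_edges = list(np.linspace(gene.end, gene.start, layout.body_bins + 1))
        down_edges = [gene.start - i * layout.flank_bin for i in range(layout.flank_bins + 1)]
    row = []
    for edges in (up_edges, body_edges, down_edges):
        for a, b in zip(edges[:-1], edges[1:]):
            row.append(mean_over(min(a, b), max(a, b)))
    return np.array(row)


class TestBuildScaledMatrix:
    def test_uniform_coverage_fills_every_cell(self, uniform_track):
        ann = od.GenomeAnnotation(
            genes=[od.GeneModel("g", "chr1", 6000, 12000, "+")], chrom_sizes={"chr1": 20000}
        )
        m = od.build_scaled_matrix(uniform_track(3.5), universe_of(ann), ann)
        assert np.allclose(m.values.to_numpy(), 3.5)

    def test_body_only_coverage_log2(self):
        ann = od.GenomeAnnotation(
            genes=[od.GeneModel("g", "chr1", 6000, 12000, "+")], chrom_sizes={"chr1": 20000}
        )
        t = make_track({"chr1": 20000}, {"chr1": [(6000, 12000, 4.0)]})
        layout = od.RegionLayout()
        m = od.build_scaled_matrix(t, universe_of(ann), ann, layout).log2()
        row = m.values.iloc[0].to_numpy()
        fb = layout.flank_bins
        assert np.allclose(row[fb : fb + layout.body_bins], np.log2(5.0))
        assert np.allclose(row[:fb], 0.0) and np.allclose(row[fb + layout.body_bins :], 0.0)

    @pytest.mark.parametrize("strand,expected", [("+", (1.0, 2.0, 3.0)), ("-", (3.0, 2.0, 1.0))])
    def test_strand_orientation_of_body_bins(self, strand, expected):
        ann = od.GenomeAnnotation(
            genes=[od.GeneModel("g", "chr1", 6000, 9000, strand)], chrom_sizes={"chr1": 20000}
        )
        t = make_track(
            {"chr1": 20000},
            {"chr1": [(6000, 7000, 1.0), (7000, 8000, 2.0), (8000, 9000, 3.0)]},
        )
        layout = od.RegionLayout(body_bins=3)
        m = od.build_scaled_matrix(t, universe_of(ann), ann, layout)
        fb = layout.flank_bins
        assert tuple(m.values.iloc[0, fb : fb + 3]) == expected

    def test_matches_per_base_oracle_on_random_genes(self):
        """Run-length binning equals per-base averaging to 1e-9 on both strands."""
        rng = np.random.default_rng(3)
        layout = od.RegionLayout(body_bins=25, flank=1000, flank_bin=50)
        for trial in range(25):
            length = int(rng.integers(2000, 10000))
            start = int(rng.integers(1500, 3000))
            strand = "+" if trial % 2 == 0 else "-"
            size = start + length + 3000
            gene = od.GeneModel("g", "chr1", start, start + length, strand)
            ann = od.GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": size})
            n_iv = int(rng.integers(1, 12))
            pts = np.sort(rng.integers(0, size, 2 * n_iv))
            ivs = [
                (int(a), int(b), float(rng.uniform(0, 10)))
                for a, b in zip(pts[0::2], pts[1::2])
                if b > a
            ]
            track = make_track({"chr1": size}, {"chr1": ivs or [(0, 1, 0.0)]})
            m = od.build_scaled_matrix(track, universe_of(ann), ann, layout)
            oracle = brute_force_row(dense_coverage(track, "chr1"), gene, layout)
            assert np.allclose(m.values.iloc[0].to_numpy(), oracle, atol=1e-9)

    def test_body_bin_conservation(self):
        """Sum of body-bin means x bin width equals the body coverage area."""
        rng = np.random.default_rng(5)
        gene = od.GeneModel("g", "chr1", 5000, 5000 + 3333, "+")
        ann = od.GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": 20000})
        ivs = [(5000 + i * 333, 5000 + (i + 1) * 333, float(rng.uniform(0, 5))) for i in range(10)]
        track = make_track({"chr1": 20000}, {"chr1": ivs})
        layout = od.RegionLayout(body_bins=7)
        m = od.build_scaled_matrix(track, universe_of(ann), ann, layout)
        fb = layout.flank_bins
        bin_width = gene.length / layout.body_bins
        body_area = m.values.iloc[0, fb : fb + 7].sum() * bin_width
        f = track.window_integrals("chr1", np.array([gene.start, gene.end]))
        assert body_area == pytest.approx(f[1] - f[0], rel=1e-9)


class TestFoldChange:
    def _mat(self, values, layout=None):
        layout = layout or od.RegionLayout()
        return od.OccupancyMatrix("s", "polII", pd.DataFrame(values), layout)

    def test_identical_matrices_zero_fc(self):
        m = self._mat([[1.0, 2.0], [3.0, 4.0]])
        fc = od.pairwise_log2fc(m, m)
        assert np.allclose(fc.values, 0.0)

    def test_hand_value_with_pseudocount(self):
        wt = self._mat([[1.0]])
        null = self._mat([[2.0]])
        fc = od.pairwise_log2fc(null, wt)  # delta = 1 -> log2(3/2)
        assert fc.values.iloc[0, 0] == pytest.approx(np.log2(1.5))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = self._mat(rng.uniform(0, 5, (4, 6)))
        b = self._mat(rng.uniform(0, 5, (4, 6)))
        assert np.allclose(od.pairwise_log2fc(a, b).values, -od.pairwise_log2fc(b, a).values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            od.pairwise_log2fc(self._mat([[1.0, 2.0]]), self._mat([[1.0]]))

    def test_log_transformed_input_rejected(self):
        m = self._mat([[1.0]])
        with pytest.raises(ValidationError):
            od.pairwise_log2fc(m.log2(), m)


class TestSummarizeRegions:
    def _setup(self, ivs, strand="+", start=6000, end=12000, size=20000):
        gene = od.GeneModel("g", "chr1", start, end, strand)
        ann = od.GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": size})
        track = make_track({"chr1": size}, {"chr1": ivs})
        return gene, ann, track

    def test_uniform_coverage_equal_summaries(self):
        _, ann, track = self._setup([(0, 20000, 2.5)])
        s = od.summarize_regions(track, universe_of(ann), ann).iloc[0]
        assert np.allclose(s[["upstream", "tss", "body", "tes", "downstream"]], 2.5)

    def test_tss_concentrated_coverage_leaves_body_and_tes_zero(self):
        _, ann, track = self._setup([(5750, 6250, 8.0)])  # exactly [TSS-250, TSS+250)
        s = od.summarize_regions(track, universe_of(ann), ann).iloc[0]
        assert s["tss"] == 8.0 and s["body"] == 0.0 and s["tes"] == 0.0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stepwise_coverage_matches_per_base_oracle(self, strand):
        rng = np.random.default_rng(11)
        ivs = [(int(a), int(a) + 400, float(rng.uniform(0, 6))) for a in range(3000, 15000, 400)]
        gene, ann, track = self._setup(ivs, strand=strand)
        s = od.summarize_regions(track, universe_of(ann), ann).iloc[0]
        dense = np.zeros(20000)
        for a, b, v in ivs:
            dense[a:b] = v
        tss, tes = gene.tss, gene.tes
        lo, hi = (min(tss, tes), max(tss, tes))
        if strand == "+":
            expected = {
                "upstream": dense[tss - 2000 : tss].mean(),
                "tss": dense[tss - 250 : tss + 250].mean(),
                "body": dense[tss + 250 : tes - 250].mean(),
                "tes": dense[tes - 250 : tes + 250].mean(),
                "downstream": dense[tes : tes + 2000].mean(),
            }
        else:
            expected = {
                "upstream": dense[tss : tss + 2000].mean(),
                "tss": dense[tss - 250 : tss + 250].mean(),
                "body": dense[tes + 250 : tss - 250].mean(),
                "tes": dense[tes - 250 : tes + 250].mean(),
                "downstream": dense[tes - 2000 : tes].mean(),
            }
        for k, v in expected.items():
            assert s[k] == pytest.approx(v, abs=1e-9), k

    def test_window_collision_names_gene(self):
        gene = od.GeneModel("tiny", "chr1", 5000, 5400, "+")
        ann = od.GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": 20000})
        track = make_track({"chr1": 20000}, {"chr1": [(0, 20000, 1.0)]})
        with pytest.raises(ValidationError, match="tiny"):
            od.summarize_regions(track, universe_of(ann), ann)


class TestMetagene:
    def _mat(self, values, index=None):
        df = pd.DataFrame(values, index=index)
        return od.OccupancyMatrix("s", "polII", df, od.RegionLayout())

    def test_single_gene_profile_is_its_row(self):
        m = self._mat([[1.0, 2.0, 3.0]], index=["g0"])
        profile, n = od.metagene_profile(m)
        assert np.allclose(profile, [1, 2, 3]) and n == 1

    def test_opposite_profiles_cancel(self):
        m = self._mat([[1.0, -2.0], [-1.0, 2.0]], index=["a", "b"])
        profile, _ = od.metagene_profile(m)
        assert np.allclose(profile, 0.0)

    def test_cluster_restricted_profile_matches_row_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 5))
        ids = [f"g{i}" for i in range(10)]
        m = self._mat(vals, index=ids)
        subset = ["g1", "g4", "g7"]
        profile, n = od.metagene_profile(m, gene_ids=subset)
        assert n == 3 and np.allclose(profile, vals[[1, 4, 7]].mean(axis=0))

    def test_empty_selection_rejected(self):
        m = self._mat([[1.0]], index=["g0"])
        with pytest.raises(ValidationError):
            od.metagene_profile(m, gene_ids=[])


class TestStrandReflection:
    def test_matrix_invariant_under_coordinate_reflection(self):
        """Reflecting track + annotation about the chromosome midpoint and
        flipping strand leaves the scale-regions matrix unchanged."""
        size = 24000
        rng = np.random.default_rng(9)
        ivs = [(int(a), int(a) + 300, float(rng.uniform(0, 4))) for a in range(2000, 20000, 600)]
        gene = od.GeneModel("g", "chr1", 7000, 13000, "+")
        ann = od.GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": size})
        track = make_track({"chr1": size}, {"chr1": ivs})

        r_ivs = [(size - b, size - a, v) for a, b, v in ivs]
        r_gene = od.GeneModel("g", "chr1", size - 13000, size - 7000, "-")
        r_ann = od.GenomeAnnotation(genes=[r_gene], chrom_sizes={"chr1": size})
        r_track = make_track({"chr1": size}, {"chr1": r_ivs})

        layout = od.RegionLayout(body_bins=20, flank=1000)
        m = od.build_scaled_matrix(track, universe_of(ann), ann, layout)
        rm = od.build_scaled_matrix(r_track, universe_of(r_ann), r_ann, layout)
        assert np.allclose(m.values.to_numpy(), rm.values.to_numpy(), atol=1e-9)
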