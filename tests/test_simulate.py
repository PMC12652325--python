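"""Generator contracts: determinism, planted filter violations, closed-form
calibration of fragment counts and effect sizes, expression ordering."""

import dataclasses

import numpy as np
import pytest

import occudelta as od
from occudelta.models import ValidationError
from occudelta.simulate import SimulationDesign


def design(**kw):
    base = dict(n_genes=120, seed=5)
    base.update(kw)
    return SimulationDesign(**base)


class TestGenerateAnnotation:
    def test_planted_filter_violations_are_exact_counts(self):
        d = design(n_genes=1000, fraction_short=0.2, fraction_close=0.0, fraction_unoccupied=0.0)
        ann, truth = od.generate_annotation(d)
        short = [g for g in ann.genes if g.length <= 2000]
        assert len(short) == 200
        assert (truth.filter_reason == "short").sum() == 200

    def test_zero_fractions_make_every_gene_pass_geometry(self):
        d = design(fraction_short=0.0, fraction_close=0.0, fraction_unoccupied=0.0)
        ann, truth = od.generate_annotation(d)
        uni = od.filter_gene_universe(ann, {g.gene_id for g in ann.genes})
        assert uni.n == len(ann.genes)
        assert len(truth.intended_universe) == len(ann.genes)

    def test_close_pairs_fail_gap_filter_only(self):
        d = design(fraction_close=0.1, fraction_short=0.0, fraction_unoccupied=0.0)
        ann, truth = od.generate_annotation(d)
        from occudelta.universe import neighbor_gaps

        gaps = neighbor_gaps(ann)
        close = truth.filter_reason[truth.filter_reason == "close"].index
        assert len(close) == 12
        assert (gaps[close] < 2000).all()
        others = truth.filter_reason[truth.filter_reason == "none"].index
        assert (gaps[others] >= 2000).all()

    def test_same_seed_identical_output(self):
        d = design()
        a1, t1 = od.generate_annotation(d)
        a2, t2 = od.generate_annotation(d)
        assert a1.genes == a2.genes
        assert t1.labels.equals(t2.labels)
        assert all(t1.multipliers[m].equals(t2.multipliers[m]) for m in t1.multipliers)

    def test_cluster_proportions_respected(self):
        d = design(n_genes=1000, fraction_short=0.0, fraction_close=0.0, fraction_unoccupied=0.0)
        _, truth = od.generate_annotation(d)
        sizes = truth.labels.value_counts()
        assert sizes["II"] > sizes["I"] > sizes["III"]
        assert sizes.sum() == 1000

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="chrom_length"):
            od.generate_annotation(design(chrom_length=10000))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            SimulationDesign(n_genes=5)


class TestSimulateChip:
    def test_same_seed_identical_tracks(self, small_dataset):
        d = small_dataset["design"]
        tracks2, tf2, _ = od.simulate_chip_experiment(
            small_dataset["annotation"], small_dataset["truth"], d
        )
        for sid, (t, s) in small_dataset["tracks"].items():
            assert t.equal(tracks2[sid][0]) and s.equal(tracks2[sid][1])
        assert tf2 == small_dataset["true_factors"]

    def test_null_effects_give_zero_mean_fold_change(self):
        effects = {"I": {}, "II": {}, "III": {}}
        d = design(
            n_genes=150,
            effects=effects,
            effect_sd=0.0,
            aff4_flank_sd=0.0,
            modalities=("polII",),
            spikein_multipliers=(1.0,) * 6,
        )
        ann, truth = od.generate_annotation(d)
        tracks, _, samples = od.simulate_chip_experiment(ann, truth, d)
        uni = od.GeneUniverse(gene_ids=list(truth.intended_universe), outcomes=None)
        by_key = {(s.pair_id, s.genotype): s.sample_id for s in samples}
        fcs = []
        for p in sorted({s.pair_id for s in samples}):
            n = od.summarize_regions(tracks[by_key[(p, "null")]][0], uni, ann)
            w = od.summarize_regions(tracks[by_key[(p, "WT")]][0], uni, ann)
            fcs.append(np.log2((n["body"] + 1e-9) / (w["body"] + 1e-9)).mean())
        assert abs(np.mean(fcs)) < 0.05

    def test_planted_body_multiplier_recovered(self):
        """Body multiplier 0.5 -> realized mean body log2FC = -1 within 0.1."""
        effects = {"III": {"polII": {"body": 0.5}}}
        d = design(
            n_genes=300,
            cluster_proportions=(("III", 1.0),),
            cluster_rho=(("III", 0.0),),
            fraction_short=0.0,
            fraction_close=0.0,
            fraction_unoccupied=0.0,
            modalities=("polII",),
            effects=effects,
            effect_sd=0.0,
        )
        ann, truth = od.generate_annotation(d)
        tracks, _, samples = od.simulate_chip_experiment(ann, truth, d)
        normalized, _ = od.normalize_samples(tracks, samples)
        uni = od.GeneUniverse(gene_ids=list(truth.intended_universe), outcomes=None)
        by_key = {(s.pair_id, s.genotype): s.sample_id for s in samples}
        vals = []
        for p in sorted({s.pair_id for s in samples}):
            n = od.summarize_regions(normalized[by_key[(p, "null")]], uni, ann)
            w = od.summarize_regions(normalized[by_key[(p, "WT")]], uni, ann)
            vals.append(np.log2((n["body"] + 1e-9) / (w["body"] + 1e-9)).mean())
        assert np.mean(vals) == pytest.approx(-1.0, abs=0.1)

    def test_expected_counts_match_closed_form(self):
        """Monte-Carlo mean of body fragment counts matches depth x weight x
        mass within 3 standard errors (analytic calibration)."""
        d = design(
            n_genes=40,
            modalities=("polII",),
            fraction_short=0.0,
            fraction_close=0.0,
            fraction_unoccupied=0.0,
            effects={"I": {}, "II": {}, "III": {}},
            effect_sd=0.0,
            aff4_flank_sd=0.0,
            spikein_multipliers=(1.0,) * 6,
            n_pairs=2,
        )
        ann, truth = od.generate_annotation(d)
        masses = d.component_masses()
        reps = []
        for seed in range(200):
            d_i = dataclasses.replace(d, seed=seed)
            tracks, _, samples = od.simulate_chip_experiment(ann, truth, d_i)
            t = tracks[samples[0].sample_id][0]
            # body-only expected area: sum over genes of count * fragment_length
            reps.append(t.area())
        total_mass = sum(masses["polII"].values())
        expected_area = (
            d.depth * truth.baseline_weight.sum() * total_mass * d.fragment_length
        )
        reps = np.array(reps)
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - expected_area) < 3 * se + 1e-9

    def test_zero_depth_rejected(self):
        with pytest.raises(ValidationError):
            SimulationDesign(n_genes=50, depth=0.0)


class TestSimulateRna:
    def test_multipliers_of_one_give_unit_ratio(self):
        # balanced clusters so every per-cluster median has a stable n
        d = design(
            n_genes=500,
            rna_multipliers=(("I", 1.0), ("II", 1.0), ("III", 1.0)),
            cluster_proportions=(("I", 1 / 3), ("II", 1 / 3), ("III", 1 / 3)),
        )
        ann, truth = od.generate_annotation(d)
        e = od.simulate_rnaseq_counts(ann, truth, d)
        wt = e.counts[e.samples_of("WT")].mean(axis=1)
        nu = e.counts[e.samples_of("null")].mean(axis=1)
        ratio = (nu + 1) / (wt + 1)
        for lab in ("I", "II", "III"):
            assert ratio.loc[truth.cluster_genes(lab)].median() == pytest.approx(1.0, abs=0.05)

    def test_planted_ordering_of_expression_change(self):
        d = design(n_genes=600, seed=2)
        ann, truth = od.generate_annotation(d)
        e = od.simulate_rnaseq_counts(ann, truth, d)
        wt = e.counts[e.samples_of("WT")].mean(axis=1)
        nu = e.counts[e.samples_of("null")].mean(axis=1)
        ratio = (nu + 1) / (wt + 1)
        med = {lab: float(ratio.loc[truth.cluster_genes(lab)].median()) for lab in ("I", "II", "III")}
        assert med["III"] < med["II"] < 1.0 < med["I"]

    def test_cluster_three_has_highest_baseline_expression(self):
        d = design(n_genes=600, seed=2)
        ann, truth = od.generate_annotation(d)
        e = od.simulate_rnaseq_counts(ann, truth, d)
        wt = e.counts[e.samples_of("WT")].mean(axis=1)
        means = {lab: float(wt.loc[truth.cluster_genes(lab)].mean()) for lab in ("I", "II", "III")}
        assert means["III"] > max(means["I"], means["II"])

    def test_same_seed_identical_counts(self):
        d = design()
        ann, truth = od.generate_annotation(d)
        a = od.simulate_rnaseq_counts(ann, truth, d)
        b = od.simulate_rnaseq_counts(ann, truth, d)
        assert a.counts.equals(b.counts)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            SimulationDesign(n_genes=50, rna_dispersion=0.0)


class TestWriteDataset:
    def test_file_inventory_and_determinism(self, tmp_path):
        d = design(n_genes=30, n_pairs=3)
        p1 = od.write_dataset(d, tmp_path / "a")
        od.write_dataset(d, tmp_path / "b")
        # 3 pairs x 3 modalities x 2 genotypes = 18 target + 18 spike-in tracks
        assert len(list((tmp_path / "a").glob("*.target.bedgraph"))) == 18
        assert len(list((tmp_path / "a").glob("*.spikein.bedgraph"))) == 18
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
        samples = od.read_sample_sheet(p1["sample_sheet"])
        assert sum(1 for s in samples if s.modality == "RNA") == 12
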