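"""Pair selection, clustering, canonical labels, median-of-ratios and the
per-cluster summaries."""

import numpy as np
import pandas as pd
import pytest

import occudelta as od
from occudelta.models import ValidationError
from occudelta.occupancy import FoldChangeMatrix


def fc(pair_id, values):
    return FoldChangeMatrix(
        pair_id=pair_id, modality="polII", values=pd.DataFrame(values), layout=od.RegionLayout()
    )


class TestSelectPairs:
    def test_top_scores_win(self):
        mats = [fc("p1", [[0.1]]), fc("p2", [[0.5]]), fc("p3", [[-0.6]])]
        assert od.select_pairs(mats, 2) == ["p2", "p3"]

    def test_tie_broken_by_pair_id(self):
        mats = [fc("p3", [[0.2]]), fc("p1", [[0.2]]), fc("p2", [[0.2]])]
        assert od.select_pairs(mats, 2) == ["p1", "p2"]

    def test_zero_matrix_never_beats_nonzero(self):
        mats = [fc("p1", [[0.0, 0.0]]), fc("p2", [[0.01, 0.0]])]
        assert od.select_pairs(mats, 1) == ["p2"]

    def test_scores_sum_over_modalities(self):
        mats = [
            fc("p1", [[1.0]]),
            FoldChangeMatrix("p1", "AFF4", pd.DataFrame([[0.0]]), od.RegionLayout()),
            fc("p2", [[0.6]]),
            FoldChangeMatrix("p2", "AFF4", pd.DataFrame([[0.6]]), od.RegionLayout()),
        ]
        assert od.select_pairs(mats, 1) == ["p2"]  # 1.2 > 1.0

    def test_too_many_requested(self):
        with pytest.raises(ValidationError):
            od.select_pairs([fc("p1", [[0.1]])], 2)


class TestClusterGenes:
    def test_recovers_separated_point_masses(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels_true = np.repeat([0, 1, 2], 20)
        X = centers[labels_true]
        features = pd.DataFrame(X, index=[f"g{i}" for i in range(60)], columns=["a", "b"])
        asg = od.cluster_genes(features, k=3)
        # within-group distance zero -> perfect recovery up to label names
        for lab in range(3):
            got = asg.labels[labels_true == lab]
            assert got.nunique() == 1

    def test_k_one_puts_all_genes_together(self):
        features = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        asg = od.cluster_genes(features, k=1)
        assert asg.labels.nunique() == 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            od.cluster_genes(pd.DataFrame([[1.0], [2.0]]), k=3)

    def test_non_finite_feature_names_gene(self):
        features = pd.DataFrame([[1.0], [np.nan]], index=["good", "bad"])
        with pytest.raises(ValidationError, match="bad"):
            od.cluster_genes(features, k=2)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        features = pd.DataFrame(rng.normal(size=(50, 4)))
        a = od.cluster_genes(features, k=3).labels
        b = od.cluster_genes(features, k=3).labels
        assert a.equals(b)


class TestLabelClusters:
    def _assignment(self, raw_labels):
        labels = pd.Series(raw_labels, index=[f"g{i}" for i in range(len(raw_labels))])
        return od.ClusterAssignment(labels=labels, features=pd.DataFrame(index=labels.index))

    def test_labels_follow_body_depletion_ordering(self):
        asg = self._assignment(["C0", "C0", "C1", "C1", "C2", "C2"])
        body = pd.Series([-0.05, -0.05, -1.2, -1.2, -0.4, -0.4], index=asg.labels.index)
        out = od.label_clusters(asg, body)
        assert out.labels.tolist() == ["I", "I", "III", "III", "II", "II"]

    def test_tied_means_raise(self):
        asg = self._assignment(["C0", "C1", "C2"])
        body = pd.Series([-0.5, -0.5, -1.0], index=asg.labels.index)
        with pytest.raises(ValidationError, match="tie"):
            od.label_clusters(asg, body)

    def test_requires_three_clusters(self):
        asg = self._assignment(["C0", "C1"])
        with pytest.raises(ValidationError):
            od.label_clusters(asg, pd.Series([0.0, -1.0], index=asg.labels.index))


class TestMedianRatio:
    def _summaries(self, ratios_by_pair, wt_value=1.0):
        """Build null/WT summary tables realizing given body ratios (delta=0
        cancels out by using large values)."""
        genes = [f"g{i}" for i in range(len(next(iter(ratios_by_pair.values()))))]
        null_s, wt_s = {}, {}
        for pid, ratios in ratios_by_pair.items():
            base = 1e6  # large values make the pseudocount negligible
            wt_s[pid] = pd.DataFrame({"body": [base] * len(genes)}, index=genes)
            null_s[pid] = pd.DataFrame({"body": [base * r for r in ratios]}, index=genes)
        return null_s, wt_s

    def test_odd_count_median(self):
        null_s, wt_s = self._summaries({"p1": [0.5], "p2": [1.0], "p3": [2.0]})
        mr = od.median_ratio_per_gene(null_s, wt_s, "polII", "body", pseudocount=1e-9)
        assert mr.median.iloc[0] == pytest.approx(1.0)

    def test_descending_ratios(self):
        null_s, wt_s = self._summaries({"p1": [0.2], "p2": [0.4], "p3": [0.8]})
        mr = od.median_ratio_per_gene(null_s, wt_s, "polII", "body", pseudocount=1e-9)
        assert mr.median.iloc[0] == pytest.approx(0.4)

    def test_even_count_uses_mean_of_middle_two(self):
        null_s, wt_s = self._summaries({"p1": [0.2], "p2": [0.4], "p3": [0.6], "p4": [0.8]})
        mr = od.median_ratio_per_gene(null_s, wt_s, "polII", "body", pseudocount=1e-9)
        assert mr.median.iloc[0] == pytest.approx(0.5)

    def test_pair_order_invariance(self):
        ratios = {"p1": [0.3, 1.2], "p2": [0.9, 0.8], "p3": [0.5, 1.5]}
        null_s, wt_s = self._summaries(ratios)
        a = od.median_ratio_per_gene(null_s, wt_s, "polII", "body").median
        shuffled_null = {k: null_s[k] for k in ("p3", "p1", "p2")}
        shuffled_wt = {k: wt_s[k] for k in ("p3", "p1", "p2")}
        b = od.median_ratio_per_gene(shuffled_null, shuffled_wt, "polII", "body").median
        assert a.equals(b)

    def test_missing_pair_rejected(self):
        null_s, wt_s = self._summaries({"p1": [0.5], "p2": [1.0]})
        del wt_s["p2"]
        with pytest.raises(ValidationError):
            od.median_ratio_per_gene(null_s, wt_s, "polII", "body")


class TestFractionDecreased:
    def test_all_decreased(self):
        assert od.fraction_decreased(pd.Series([0.5, 0.5, 0.5])) == 1.0

    def test_exactly_one_is_not_decreased(self):
        assert od.fraction_decreased(pd.Series([1.0, 1.0])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            od.fraction_decreased(pd.Series(dtype=float))


class TestSpearmanByCluster:
    def _assignment(self, n, label="I"):
        labels = pd.Series([label] * n, index=[f"g{i}" for i in range(n)])
        return od.ClusterAssignment(labels=labels, features=pd.DataFrame(index=labels.index))

    def test_monotone_pair_gives_rho_one(self):
        asg = self._assignment(6)
        x = pd.Series(np.arange(6.0), index=asg.labels.index)
        res = od.spearman_by_cluster(x, x * 3 + 1, asg)
        assert res[0].rho == pytest.approx(1.0)

    def test_small_cluster_rejected(self):
        asg = self._assignment(2)
        x = pd.Series([1.0, 2.0], index=asg.labels.index)
        with pytest.raises(ValidationError):
            od.spearman_by_cluster(x, x, asg)


class TestCompareClusterExpression:
    def _table(self, wt_means, null_means, label="I"):
        """Counts realizing given gene-level means; a ballast gene outside the
        cluster equalizes library sizes so RPM preserves the planted means."""
        genes = [f"g{i}" for i in range(len(wt_means))]
        total = max(sum(wt_means), sum(null_means)) * 10
        cols = {}
        genotypes = {}
        for r in range(2):  # two identical replicates realize the gene means
            cols[f"wt{r}"] = list(wt_means) + [total - sum(wt_means)]
            genotypes[f"wt{r}"] = "WT"
            cols[f"nu{r}"] = list(null_means) + [total - sum(null_means)]
            genotypes[f"nu{r}"] = "null"
        counts = pd.DataFrame(cols, index=genes + ["ballast"], dtype=float).astype(int)
        expr = od.ExpressionTable(counts=counts, genotypes=genotypes)
        labels = pd.Series([label] * len(genes), index=genes)
        asg = od.ClusterAssignment(labels=labels, features=pd.DataFrame(index=genes))
        return expr, asg

    def test_complete_separation_exact_p(self):
        """Gene-level means (1,2,3) vs (10,20,30)-scale: exact two-sided
        P = 2/C(6,3) = 0.1 at complete separation."""
        expr, asg = self._table([100, 200, 300], [1000, 2000, 3000])
        out = od.compare_cluster_expression(expr, asg)
        assert out.loc["I", "pvalue"] == pytest.approx(0.1)
        assert out.loc["I", "median_ratio"] > 1

    def test_no_effect_p_one(self):
        expr, asg = self._table([10, 20, 30], [10, 20, 30])
        out = od.compare_cluster_expression(expr, asg)
        assert out.loc["I", "pvalue"] == 1.0

    def test_all_tied_input_warns(self):
        expr, asg = self._table([5, 5, 5], [5, 5, 5])
        with pytest.warns(UserWarning, match="tied"):
            out = od.compare_cluster_expression(expr, asg)
        assert out.loc["I", "pvalue"] == 1.0

    def test_direction_reported(self, small_dataset):
        """Cluster III shows the most negative expression change."""
        d = small_dataset
        labels = d["truth"].labels
        universe = labels[labels != "filtered"]
        asg = od.ClusterAssignment(labels=universe, features=pd.DataFrame(index=universe.index))
        out = od.compare_cluster_expression(d["expression"], asg)
        assert out["median_ratio"].idxmin() == "III"
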