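"""Degree curves, O/E analysis, stratified bins, rank-sum and ROC."""

import itertools
import math

import numpy as np
import pytest

from phosphoppi import degree_statistics as ds
from phosphoppi.identifiers_io import CovariateTable
from conftest import make_net


class TestDegreeCurve:
    def test_all_degree_one(self):
        c = ds.curve_from_degrees([1, 1, 1], k_max=2)
        assert c.at(1) == 1.0 and c.at(2) == 0.0

    def test_direct_count(self):
        c = ds.curve_from_degrees([1, 2, 3])
        assert c.at(2) == pytest.approx(2 / 3)

    def test_monotone_and_integer_counts(self, coupling_net):
        for group in ("phospho", "nonphospho"):
            c = ds.degree_curve(coupling_net, group)
            assert np.all(np.diff(c.p_ge) <= 0)
            assert c.p_ge[0] == 1.0
            counts = c.p_ge * c.group_size
            assert np.allclose(counts, np.round(counts))

    def test_empty_group_errors(self):
        net = make_net([("A", "B")], {"A", "B"})
        with pytest.raises(ValueError):
            ds.degree_curve(net, "nonphospho")


class TestPnRatio:
    def test_identical_curves_give_unity(self):
        c = ds.curve_from_degrees([1, 2, 3])
        assert all(v == 1.0 for v in ds.pn_ratio(c, c).values())

    def test_printed_proportions_ratio(self):
        """0.679/0.476, the published phospho vs nonphospho shares at k=3."""
        assert 0.679 / 0.476 == pytest.approx(1.43, abs=0.005)

    def test_zero_denominator_absent(self):
        p = ds.curve_from_degrees([1, 2, 3])
        n = ds.curve_from_degrees([1, 1, 1], k_max=3)
        assert 3 in ds.pn_ratio(p, p)
        assert 3 not in ds.pn_ratio(p, n)


class TestOEAnalysis:
    def test_random_labels_near_null(self, rng):
        """Labels assigned uniformly at random: O/E ~ 1 and ns at low k."""
        import networkx as nx
        from phosphoppi.network import PhosphoPPI

        g = nx.barabasi_albert_graph(400, 3, seed=5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        labs = rng.random(400) < 0.5
        for v, l in zip(g.nodes, labs):
            g.nodes[v]["phospho"] = bool(l)
        net = PhosphoPPI(g)
        rows = ds.oe_analysis(net, 300, seed=9)
        r = next(r for r in rows if r.k == 4)
        assert r.stars == "ns"
        assert abs(r.oe - 1.0) < 0.1
        for row in rows:
            if not math.isnan(row.oe):
                assert row.ci_low <= row.expected_mean <= row.ci_high

    def test_planted_coupling_detected(self, coupling_net):
        rows = ds.oe_analysis(coupling_net, 300, seed=2)
        r = next(r for r in rows if r.k == 10)
        assert r.oe > 1.0

    def test_ci_requires_replicates(self, coupling_net):
        with pytest.raises(ValueError):
            ds.oe_analysis(coupling_net, 50, seed=0)


class TestRankSum:
    def test_identical_samples(self):
        assert ds.rank_sum([1, 2], [1, 2]) == 1.0

    def test_fully_separated_exact(self):
        # most extreme of C(6,3)=20 arrangements, two-sided
        assert ds.rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ds.rank_sum([], [1.0])

    @staticmethod
    def enumeration_oracle(a, b):
        """Exact two-sided p by brute-force enumeration of group splits."""
        pooled = sorted(a) + sorted(b)
        n_a = len(a)
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        w_obs = sum(ranks[v] for v in a)
        ws = [
            sum(ranks[pooled[i]] for i in comb)
            for comb in itertools.combinations(range(len(pooled)), n_a)
        ]
        n = len(ws)
        ge = sum(w >= w_obs for w in ws) / n
        le = sum(w <= w_obs for w in ws) / n
        return min(1.0, 2 * min(ge, le))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(1, 5))
        n_b = int(rng.integers(1, 5))
        values = rng.permutation(20)[: n_a + n_b].astype(float)
        a, b = list(values[:n_a]), list(values[n_a:])
        assert ds.rank_sum(a, b) == pytest.approx(self.enumeration_oracle(a, b))

    def test_tied_degenerate_input(self):
        assert ds.rank_sum([3, 3], [3, 3, 3]) == 1.0


class TestStratifiedComparison:
    def net_with_covariate(self, values):
        edges = []
        names = list(values)
        for i, v in enumerate(names):
            edges.append((v, f"X{i}"))  # pendant, keeps every node degree >= 1
        net = make_net(edges, {v for v in names if v.startswith("P")})
        table = CovariateTable("abundance")
        table.entries = dict(values)
        return net, table

    def test_log10_binning(self):
        net, table = self.net_with_covariate({"P1": 1000.0, "N1": 1200.0})
        bins = ds.stratified_comparison(net, table, "log10", 0.5)
        assert len(bins) == 1
        assert bins[0].bin_start == pytest.approx(3.0)
        assert bins[0].n_phospho == 1 and bins[0].n_nonphospho == 1

    def test_half_open_convention(self):
        table = CovariateTable("disorder")
        table.entries = {"P1": 0.40, "N1": 0.39}
        net = make_net([("P1", "X0"), ("N1", "X1")], {"P1"})
        bins = ds.stratified_comparison(net, table, "identity", 0.2)
        starts = sorted(round(b.bin_start, 10) for b in bins)
        assert starts == [0.2, 0.4]  # 0.39 -> [0.2,0.4), 0.40 -> [0.4,0.6)

    def test_nonpositive_width_errors(self, tiny_net):
        with pytest.raises(ValueError):
            ds.stratified_comparison(tiny_net, CovariateTable("abundance"), "log10", 0.0)

    def test_single_group_bin_has_nan_p(self):
        net, table = self.net_with_covariate({"P1": 10.0})
        b = ds.stratified_comparison(net, table, "log10", 0.5)[0]
        assert math.isnan(b.ranksum_p)
        assert b.n_nonphospho == 0


class TestMultisiteCurves:
    def test_groups_partition_nodes(self, coupling_net, coupling_bundle):
        from phosphoppi.phospho_unification import unify
        from phosphoppi.identifiers_io import PhosphoRecord

        by_src = {}
        for r in coupling_bundle.phospho_records:
            by_src.setdefault(r.source, []).append(r)
        unified = unify(list(by_src.values()))
        curves = ds.multisite_curves(coupling_net, unified)
        total = sum(c.group_size for c in curves.values() if c is not None)
        assert total == coupling_net.n_nodes

    def test_all_single_site_gives_absent_multi(self):
        from phosphoppi.phospho_unification import UnifiedPhosphoSet

        net = make_net([("P1", "N1")], {"P1"})
        ups = UnifiedPhosphoSet(proteins={"P1": {(1, "S")}})
        curves = ds.multisite_curves(net, ups)
        assert curves["multi_site"] is None
        assert curves["single_site"].group_size == 1


class TestRoc:
    def test_perfect_separator(self):
        scores = {"P1": 2.0, "P2": 3.0, "N1": 0.0, "N2": 1.0}
        labels = {"P1": True, "P2": True, "N1": False, "N2": False}
        roc, _ = ds.roc_compare(scores, scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert (0.0, 1.0) in roc.points

    def test_constant_scores(self):
        scores = {"P1": 1.0, "N1": 1.0}
        labels = {"P1": True, "N1": False}
        roc, _ = ds.roc_compare(scores, scores, labels)
        assert roc.points == [(1.0, 1.0)]
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ds.roc_compare({"A": 1.0}, {"A": 2.0}, {"A": True})

    def test_mismatched_node_sets_error(self):
        with pytest.raises(ValueError):
            ds.roc_compare({"A": 1.0}, {"B": 1.0}, {"A": True, "B": False})

    @staticmethod
    def concordance_oracle(scores, labels):
        """AUC as P(score_pos > score_neg) with ties counted 1/2."""
        pos = [scores[v] for v in scores if labels[v]]
        neg = [scores[v] for v in scores if not labels[v]]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        return wins / (len(pos) * len(neg))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = {f"V{i}": bool(rng.random() < 0.5) for i in range(n)}
        if len(set(labels.values())) < 2:
            labels["V0"], labels["V1"] = True, False
        scores = {
            v: float(labels[v]) + rng.normal(0, 1) for v in labels
        }
        # discretize some scores to force ties
        scores = {v: round(s, 1) for v, s in scores.items()}
        roc, _ = ds.roc_compare(scores, scores, labels)
        assert roc.auc == pytest.approx(self.concordance_oracle(scores, labels))
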