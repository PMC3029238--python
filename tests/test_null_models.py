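"""Contracts of the NLS and RER null models and empirical p-values."""

import numpy as np
import pytest

from phosphoppi import null_models as nm
from conftest import make_net


def star_net():
    # K1,3: hub H phosphorylated
    return make_net([("H", "A"), ("H", "B"), ("H", "C")], {"H"})


class TestNodeLabelShuffle:
    def test_topology_preserved(self, coupling_net, rng):
        out = nm.node_label_shuffle(coupling_net, rng)
        assert out.n_edges == coupling_net.n_edges
        assert sorted(d for _, d in out.graph.degree()) == sorted(
            d for _, d in coupling_net.graph.degree()
        )

    def test_label_multiset_preserved(self, coupling_net, rng):
        out = nm.node_label_shuffle(coupling_net, rng)
        assert len(out.phospho_nodes) == len(coupling_net.phospho_nodes)

    def test_star_hub_phospho_fraction_is_quarter(self, rng):
        """A uniform identity permutation puts the one phospho label on the
        hub position with probability 1/4."""
        net = star_net()
        hits = 0
        n = 4000
        for _ in range(n):
            out = nm.node_label_shuffle(net, rng)
            hub = max(out.graph.nodes, key=lambda v: out.graph.degree(v))
            hits += out.is_phospho(hub)
        assert abs(hits / n - 0.25) < 0.025

    def test_single_edge_shuffle_is_structurally_invariant(self, rng):
        """On two nodes the identity and the swap are the only permutations
        (each with probability 1/2) and both yield the same undirected edge."""
        net = make_net([("A", "B")], {"A"})
        out = nm.node_label_shuffle(net, rng)
        assert {tuple(sorted(e)) for e in out.graph.edges} == {("A", "B")}
        assert out.phospho_nodes == ["A"]

    def test_path_center_occupancy_is_third(self, rng):
        """On a 3-path the phospho protein lands on the center position with
        probability 1/3 under a uniform permutation."""
        net = make_net([("A", "B"), ("B", "C")], {"A"})
        center = sum(
            nm.node_label_shuffle(net, rng).degree("A") == 2 for _ in range(3000)
        )
        assert abs(center / 3000 - 1 / 3) < 0.03

    def test_degree_of_named_node_randomizes(self, rng):
        """Label-position decoupling: the phospho protein occupies the hub
        position in 1/4 of shuffles of a star."""
        net = star_net()
        phospho_is_hub = 0
        n = 4000
        for _ in range(n):
            out = nm.node_label_shuffle(net, rng)
            phospho_is_hub += out.degree("H") == 3
        assert abs(phospho_is_hub / n - 0.25) < 0.025


class TestRandomEdgeRewire:
    def test_triangle_is_fixed_point(self, rng):
        net = make_net([("A", "B"), ("B", "C"), ("A", "C")], set())
        out = nm.random_edge_rewire(net, rng, multiplier=50)
        assert {tuple(sorted(e)) for e in out.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }

    def test_star_is_fixed_point(self, rng):
        net = star_net()
        out = nm.random_edge_rewire(net, rng, multiplier=50)
        assert {tuple(sorted(e)) for e in out.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }

    def test_per_node_degrees_exactly_preserved(self, coupling_net, rng):
        out = nm.random_edge_rewire(coupling_net, rng, multiplier=10)
        for v in coupling_net.nodes:
            assert out.degree(v) == coupling_net.degree(v)

    def test_stays_simple_without_self_loops(self, coupling_net, rng):
        out = nm.random_edge_rewire(coupling_net, rng, multiplier=10)
        assert out.n_edges == coupling_net.n_edges  # no collapsed duplicates
        assert not any(u == v for u, v in out.graph.edges)

    def test_input_self_loops_frozen(self, rng):
        net = make_net([("A", "A"), ("A", "B"), ("B", "C"), ("C", "D")], set())
        out = nm.random_edge_rewire(net, rng, multiplier=50)
        assert ("A", "A") in [tuple(sorted(e)) for e in out.graph.edges]

    def test_single_edge_returns_copy_with_warning(self, rng):
        net = make_net([("A", "B")], set())
        with pytest.warns(UserWarning):
            out = nm.random_edge_rewire(net, rng)
        assert out.n_edges == 1

    def test_python_chain_matches_contracts(self, rng):
        """Pure-Python reference chain also preserves degrees and simplicity."""
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (0, 2), (1, 3)]
        out = nm.rewire_edges(edges, rng, multiplier=200)
        assert len(out) == len(edges)
        assert len(set(out)) == len(out)
        deg = lambda es: sorted(np.bincount(np.ravel(es), minlength=5))
        assert deg(edges) == deg(out)
        assert all(a != b for a, b in out)


class TestEmpiricalPvalue:
    def test_observed_beyond_all_nulls(self):
        p = nm.empirical_pvalue(5, [1, 2, 3, 4], "ge")
        assert p.proportion == 0.0
        assert p.label == "< 0.25"

    def test_observed_equal_to_all_nulls(self):
        assert nm.empirical_pvalue(2, [2, 2, 2], "ge").proportion == 1.0

    def test_direct_count(self):
        assert nm.empirical_pvalue(3, [1, 2, 3, 4], "ge").proportion == 0.5
        assert nm.empirical_pvalue(3, [1, 2, 3, 4], "le").proportion == 0.75

    def test_empty_nulls_error(self):
        with pytest.raises(ValueError):
            nm.empirical_pvalue(1, [], "ge")

    def test_conservative_variant(self):
        p = nm.empirical_pvalue(5, [1, 2, 3, 4], "ge")
        assert p.conservative == pytest.approx(1 / 5)

    def test_null_distributed_observed_gives_uniform_p(self):
        """p of an observed value drawn from the null distribution is uniform
        on {1/N..1} in expectation."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            draws = rng.normal(size=51)
            ps.append(nm.empirical_pvalue(draws[0], draws[1:], "ge").proportion)
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.51) < 0.05  # E[p] = (N+1)/(2N) at N=50
        assert abs((ps <= 0.25).mean() - 0.24) < 0.07


class TestEnsemble:
    def test_bitwise_reproducible(self, coupling_net):
        stat = lambda g: len(g.phospho_nodes and g.phospho_nodes)
        a = nm.ensemble(coupling_net, "NLS", lambda g: g.n_edges, 10, seed=3)
        b = nm.ensemble(coupling_net, "NLS", lambda g: g.n_edges, 10, seed=3)
        assert a.statistics == b.statistics

    def test_rer_edge_count_constant(self, coupling_net):
        ens = nm.ensemble(coupling_net, "RER", lambda g: g.n_edges, 5, seed=1, multiplier=5)
        assert ens.statistics == [coupling_net.n_edges] * 5

    def test_nls_phospho_count_constant(self, coupling_net):
        ens = nm.ensemble(coupling_net, "NLS", lambda g: len(g.phospho_nodes), 5, seed=1)
        assert ens.statistics == [len(coupling_net.phospho_nodes)] * 5

    def test_array_and_graph_ensembles_agree(self, coupling_net):
        """Fast array path and graph path compute the same statistics for the
        same seeds (NLS)."""
        def graph_stat(g):
            return sum(
                1 for u, v in g.graph.edges if g.is_phospho(u) and g.is_phospho(v)
            )

        def array_stat(u, v, ph):
            ns = u != v
            return int(np.count_nonzero(ph[u[ns]] & ph[v[ns]]))

        a = nm.ensemble(coupling_net, "NLS", graph_stat, 5, seed=11)
        b = nm.array_ensemble(coupling_net, "NLS", array_stat, 5, seed=11)
        assert a.statistics == b.statistics

    def test_statistic_failure_names_replicate(self, coupling_net):
        def bad(g):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="replicate 0"):
            nm.ensemble(coupling_net, "NLS", bad, 3, seed=0)

    def test_invalid_scheme(self, coupling_net):
        with pytest.raises(ValueError):
            nm.ensemble(coupling_net, "XXX", lambda g: 0, 2, seed=0)


def test_stars_ladder():
    assert [nm.stars(p) for p in (0.2, 0.04, 0.009, 0.0005)] == ["ns", "*", "**", "***"]
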