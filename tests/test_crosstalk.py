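"""Inter-module counting, degree-preserving rewiring, permutation p-values."""

import networkx as nx
import numpy as np
import pytest

from modcross import (
    CrosstalkResult,
    crosstalk_test,
    inter_module_edges,
    randomize_network,
    shared_elements,
)
from modcross.mcode import GeneModule

from conftest import truth_modules


def module(members, context="inflammation", ordinal=1):
    return GeneModule(
        module_id=(context, ordinal),
        context=context,
        members=frozenset(members),
        seed_gene=min(members),
        score=0.0,
    )


class TestInterModuleEdges:
    def test_enumeration_disjoint_modules(self):
        net = nx.Graph([("x", "u"), ("y", "v"), ("x", "y"), ("u", "v")])
        a = module({"x", "y"})
        b = module({"u", "v"}, "cancer")
        count, edges = inter_module_edges(net, a, b)
        assert count == 2
        assert set(edges) == {("x", "u"), ("y", "v")}

    def test_edges_touching_shared_gene_excluded(self):
        net = nx.Graph([("x", "d"), ("y", "c"), ("c", "d")])
        a = module({"x", "y", "c"})
        b = module({"c", "d"}, "cancer")
        count, edges = inter_module_edges(net, a, b)
        assert count == 1
        assert edges == [("x", "d")]

    def test_edgeless_graph_zero(self):
        net = nx.Graph()
        net.add_nodes_from("abcd")
        assert inter_module_edges(net, module({"a", "b"}), module({"c", "d"}))[0] == 0


class TestSharedElements:
    def test_identical_modules_share_everything(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        m = module({"a", "b", "c"})
        genes, edges = shared_elements(m, m, net)
        assert genes == {"a", "b", "c"}
        assert edges == {("a", "b"), ("b", "c")}

    def test_disjoint_modules_share_nothing(self):
        net = nx.Graph([("a", "b")])
        genes, edges = shared_elements(module({"a"}), module({"b"}, "cancer"), net)
        assert genes == set() and edges == set()

    def test_intersection_edge_reported(self):
        net = nx.Graph([("c", "d"), ("a", "c")])
        a = module({"a", "c", "d"})
        b = module({"c", "d", "e"}, "cancer")
        genes, edges = shared_elements(a, b, net)
        assert genes == {"c", "d"}
        assert edges == {("c", "d")}


class TestRandomizeNetwork:
    def test_triangle_is_rigid(self):
        k3 = nx.complete_graph(3)
        out = randomize_network(k3, rng_seed=1)
        assert set(map(frozenset, out.edges)) == set(map(frozenset, k3.edges))

    def test_path_degree_sequence_forced(self):
        p = nx.path_graph(3)
        for seed in range(5):
            out = randomize_network(p, rng_seed=seed)
            assert sorted(d for _, d in out.degree) == [1, 1, 2]
            assert nx.is_connected(out)

    def test_degree_multiset_preserved(self, default_study):
        _, net, _ = default_study
        out = randomize_network(net, rng_seed=77)
        assert sorted(d for _, d in out.degree) == sorted(d for _, d in net.degree)
        assert nx.number_of_selfloops(out) == 0

    def test_rewiring_changes_edges(self, default_study):
        _, net, _ = default_study
        out = randomize_network(net, rng_seed=78)
        assert set(map(frozenset, out.edges)) != set(map(frozenset, net.edges))

    def test_reproducible_given_seed(self, default_study):
        _, net, _ = default_study
        a = randomize_network(net, rng_seed=5)
        b = randomize_network(net, rng_seed=5)
        assert set(a.edges) == set(b.edges)

    def test_tiny_graph_returned_unchanged(self):
        g = nx.Graph([("a", "b")])
        out = randomize_network(g, rng_seed=0)
        assert set(out.edges) == {("a", "b")}


class TestPValueFormula:
    def make_result(self, observed, null_counts):
        counts = np.asarray(null_counts)
        p = float((counts > observed).sum() / len(counts))
        return CrosstalkResult(
            pair=(("inflammation", 1), ("cancer", 1)),
            observed_inter_edges=observed,
            null_counts=counts,
            p_value=p,
            shared_genes=frozenset(),
            shared_edges=frozenset(),
            significant=p < 0.05,
        )

    def test_fifty_of_thousand_gives_p_005(self):
        nulls = [11] * 50 + [3] * 950
        r = self.make_result(10, nulls)
        assert r.p_value == 0.05
        assert r.recount_p() == 0.05

    def test_all_null_below_observed_gives_zero(self):
        r = self.make_result(10, [10, 9, 0, 5])
        assert r.p_value == 0.0

    def test_strict_inequality_ties_do_not_count(self):
        r = self.make_result(4, [4, 4, 4, 5])
        assert r.p_value == 0.25


class TestCrosstalkTest:
    def test_planted_pair_significant_null_pairs_not(self, default_study):
        _, net, truth = default_study
        mods = truth_modules(truth)
        infl = [m for m in mods if m.context == "inflammation"]
        canc = [m for m in mods if m.context == "cancer"]
        results = crosstalk_test(net, infl, canc, n_random=100, rng_seed=3)
        assert len(results) == len(infl) * len(canc)
        by_pair = {r.pair: r for r in results}
        for (i, j) in truth.inter_edge_counts:
            pair = (mods[i].module_id, mods[j].module_id)
            assert by_pair[pair].significant
        assert all(r.p_value == r.recount_p() for r in results)

    def test_shared_ensemble_and_monotonicity(self, default_study):
        _, net, truth = default_study
        mods = truth_modules(truth)
        infl = [m for m in mods if m.context == "inflammation"]
        canc = [m for m in mods if m.context == "cancer"]
        results = crosstalk_test(net, infl[:2], canc[:2], n_random=50, rng_seed=4)
        for r in results:
            assert len(r.null_counts) == 50
            # adding an inter-edge cannot raise p against the fixed ensemble
            p_plus = float((r.null_counts > r.observed_inter_edges + 1).sum()) / 50
            assert p_plus <= r.p_value

    def test_empty_module_list_gives_empty_result(self, default_study):
        _, net, truth = default_study
        assert crosstalk_test(net, [], truth_modules(truth), n_random=10) == []

    def test_conservative_variant_never_zero(self, default_study):
        _, net, truth = default_study
        mods = truth_modules(truth)
        infl = [m for m in mods if m.context == "inflammation"][:1]
        canc = [m for m in mods if m.context == "cancer"][:1]
        results = crosstalk_test(net, infl, canc, n_random=50, rng_seed=6,
                                 conservative=True)
        assert results[0].p_value >= 1.0 / 51.0
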