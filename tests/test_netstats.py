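"""Interconnectivity, permutation null, degree and hub statistics."""

import networkx as nx
import numpy as np
import pytest

from longnet.io import DataError, EdgeRecord
from longnet.netstats import (
    degree_summary,
    hub_connectivity,
    interconnectivity,
    permutation_null,
)
from longnet.network import Interactome, build_interactome


def _graph(*edges):
    return build_interactome([EdgeRecord(a, b) for a, b in edges])


def interconnectivity_oracle(graph: nx.Graph, members: set) -> float:
    """O(|S|^2) pair scan, independent of the implementation."""
    present = [m for m in members if m in graph]
    hits = 0
    for g in present:
        if any(g != h and graph.has_edge(g, h) for h in present):
            hits += 1
    return hits / len(present)


class TestInterconnectivity:
    def test_mixed_set(self):
        inter = _graph(("a", "b"), ("c", "d"), ("a", "e"))
        res = interconnectivity(inter, {"a", "b", "c"})
        assert (res.n_present, res.n_interconnected) == (3, 2)
        assert res.fraction == pytest.approx(2 / 3)

    def test_no_internal_edge(self):
        inter = _graph(("a", "b"), ("b", "c"))
        assert interconnectivity(inter, {"a", "c"}).fraction == 0.0

    def test_clique(self):
        inter = _graph(("a", "b"))
        assert interconnectivity(inter, {"a", "b"}).fraction == 1.0

    def test_absent_members_counted_in_set_size_only(self):
        inter = _graph(("a", "b"))
        res = interconnectivity(inter, {"a", "b", "zzz"})
        assert (res.set_size, res.n_present) == (3, 2)

    def test_all_absent_errors(self):
        with pytest.raises(DataError):
            interconnectivity(_graph(("a", "b")), {"x", "y"})

    def test_matches_pair_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            inter = Interactome(graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
            members = set(
                rng.choice(sorted(inter.nodes), size=int(rng.integers(1, n + 1)),
                           replace=False)
            )
            if not members & inter.nodes:
                continue
            res = interconnectivity(inter, members)
            assert res.fraction == pytest.approx(
                interconnectivity_oracle(inter.graph, members)
            )


class TestPermutationNull:
    def test_requires_two_present(self):
        with pytest.raises(DataError):
            permutation_null(_graph(("a", "b"), ("b", "c")), {"a"}, 9, seed=0)

    def test_set_larger_than_graph(self):
        inter = _graph(("a", "b"))
        with pytest.raises(DataError):
            interconnectivity(inter, set())

    def test_complete_graph_null_indistinguishable(self):
        g = nx.complete_graph(8)
        inter = Interactome(graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
        res = permutation_null(inter, {"n0", "n1", "n2"}, 99, seed=1)
        assert res.p_value == 1.0

    def test_clique_in_sparse_graph_is_significant(self):
        g = nx.gnp_random_graph(120, 0.01, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        clique = [f"n{i}" for i in range(6)]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                g.add_edge(a, b)
        inter = Interactome(graph=g)
        res = permutation_null(inter, set(clique), 999, seed=7)
        assert res.observed == 1.0
        assert res.p_value <= 0.05

    def test_determinism_bit_identical(self):
        inter = _graph(*[(f"n{i}", f"n{i+1}") for i in range(30)])
        a = permutation_null(inter, {"n0", "n1", "n5"}, 99, seed=42)
        b = permutation_null(inter, {"n0", "n1", "n5"}, 99, seed=42)
        assert a == b

    def test_add_one_p_value_formula(self):
        inter = _graph(*[(f"n{i}", f"n{i+1}") for i in range(20)])
        res = permutation_null(inter, {"n0", "n1"}, 49, seed=0)
        expected = (1 + sum(f >= res.observed for f in res.null_fractions)) / 50
        assert res.p_value == expected
        assert 0 < res.p_value <= 1

    def test_degree_matched_mode_runs_deterministically(self):
        g = nx.barabasi_albert_graph(80, 2, seed=9)
        inter = Interactome(graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
        genes = {f"n{i}" for i in range(10)}
        a = permutation_null(inter, genes, 99, seed=3, sampling_mode="degree_matched")
        b = permutation_null(inter, genes, 99, seed=3, sampling_mode="degree_matched")
        assert a == b
        assert a.sampling_mode == "degree_matched"


class TestDegreeSummary:
    def test_triangle(self):
        assert degree_summary(_graph(("a", "b"), ("b", "c"), ("c", "a"))).mean == 2.0

    def test_star_hub(self):
        star = _graph(*[("hub", f"l{i}") for i in range(4)])
        assert degree_summary(star, {"hub"}).max == 4

    def test_subset_mean_and_absent(self):
        inter = _graph(("a", "b"), ("b", "c"))
        summary = degree_summary(inter, {"a", "c", "zzz"})
        assert summary.mean == 1.0
        assert summary.absent == {"zzz"}


class TestHubConnectivity:
    def test_counts(self):
        inter = _graph(("g1", "h1"), ("g2", "h1"), ("g2", "h2"))
        res = hub_connectivity(inter, {"g1", "g2", "g3"}, ["h1", "h2"])
        assert (res.n_any, res.n_all) == (2, 1)
        assert res.table["g2"] == {"h1", "h2"}

    def test_disconnected_hubs(self):
        inter = _graph(("a", "b"))
        res = hub_connectivity(inter, {"a", "b"}, ["h1"])
        assert (res.n_any, res.n_all) == (0, 0)

    def test_empty_inputs_error(self):
        inter = _graph(("a", "b"))
        with pytest.raises(DataError):
            hub_connectivity(inter, set(), ["h1"])
        with pytest.raises(DataError):
            hub_connectivity(inter, {"a"}, [])
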