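"""Regions, shortest paths, betweenness, centrality index, and comparison."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_weighted_graph
from fluctnet.errors import ComparisonError, DisconnectionError, ResidueLookupError
from fluctnet.pathways import (
    Region,
    average_path_length,
    band_betweenness,
    betweenness,
    centrality_index,
    compare_runs,
    define_region,
    near_optimal_paths,
    shortest_path,
)
from fluctnet.synthetic import SyntheticSpec, sample_frames


def _region(*members, anchor=None):
    return Region(
        anchor=anchor or members[0], radius=6.0, occupancy=0.75,
        members=tuple(sorted(members)),
    )


def brute_shortest(g: nx.Graph, sources, targets):
    """Exhaustive simple-path enumeration oracle: (best length, best paths)."""
    best = math.inf
    paths = []
    for s in sources:
        for t in targets:
            if s == t:
                if 0.0 < best:
                    best, paths = 0.0, [(s,)]
                continue
            if s not in g or t not in g:
                continue
            for p in nx.all_simple_paths(g, s, t):
                length = sum(g[u][v]["weight"] for u, v in zip(p[:-1], p[1:]))
                if length < best - 1e-12:
                    best, paths = length, [tuple(p)]
                elif abs(length - best) <= 1e-12:
                    paths.append(tuple(p))
    return best, paths


def brute_betweenness(g: nx.Graph, sources, targets):
    """σ_st(v)/σ_st summed over member pairs, by full path enumeration."""
    b = {v: 0.0 for v in g.nodes}
    for s in sources:
        for t in targets:
            if s == t or s not in g or t not in g:
                continue
            lengths = []
            for p in nx.all_simple_paths(g, s, t):
                lengths.append(
                    (sum(g[u][v]["weight"] for u, v in zip(p[:-1], p[1:])), tuple(p))
                )
            if not lengths:
                continue
            dmin = min(l for l, _ in lengths)
            shortest = [p for l, p in lengths if abs(l - dmin) <= 1e-9 * (1 + dmin)]
            for v in g.nodes:
                if v in (s, t):
                    continue
                b[v] += sum(1 for p in shortest if v in p) / len(shortest)
    return b


class TestShortestPath:
    def test_triangle(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        g.add_edge("a", "c", weight=2.5)
        p = shortest_path(g, _region("a"), _region("c"))
        assert p.residues == ("a", "b", "c")
        assert p.total_length == pytest.approx(2.0)

    def test_overlapping_regions_give_zero_length_path(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        p = shortest_path(g, _region("a", "b"), _region("b"))
        assert p.residues == ("b",)
        assert p.total_length == 0.0

    def test_disconnection_reports_components(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        with pytest.raises(DisconnectionError, match="component"):
            shortest_path(g, _region("a"), _region("c"))

    def test_matches_enumeration_on_random_graphs(self):
        """Dijkstra equals exhaustive enumeration on 200 random graphs."""
        rng = np.random.default_rng(2025)
        for _ in range(200):
            g = random_weighted_graph(rng)
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            expect, _ = brute_shortest(g, [s], [t])
            got = shortest_path(g, _region(s), _region(t))
            assert got.total_length == pytest.approx(expect, abs=1e-9)

    def test_independent_dijkstra_oracle(self):
        """Cross-check against scipy's sparse-graph Dijkstra."""
        from scipy.sparse.csgraph import dijkstra as sp_dijkstra

        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_weighted_graph(rng)
            nodes = sorted(g.nodes)
            m = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight")
            dist = sp_dijkstra(m, directed=False, indices=0)
            got = shortest_path(g, _region(nodes[0]), _region(nodes[-1]))
            assert got.total_length == pytest.approx(dist[len(nodes) - 1], abs=1e-9)

    def test_deterministic_lexicographic_tie_break(self):
        g = nx.Graph()
        for u, v in [("s", "b"), ("b", "t"), ("s", "c"), ("c", "t")]:
            g.add_edge(u, v, weight=1.0)
        p = shortest_path(g, _region("s"), _region("t"))
        assert p.residues == ("s", "b", "t")  # 'b' < 'c'

    def test_edge_removal_never_shortens(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            g = random_weighted_graph(rng)
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            base = shortest_path(g, _region(s), _region(t)).total_length
            edges = list(g.edges)
            u, v = edges[rng.integers(len(edges))]
            h = g.copy()
            h.remove_edge(u, v)
            try:
                pruned = shortest_path(h, _region(s), _region(t)).total_length
            except DisconnectionError:
                continue
            assert pruned >= base - 1e-12

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        g = random_weighted_graph(rng)
        nodes = sorted(g.nodes)
        mapping = {k: f"B:{i + 100}" for i, k in enumerate(nodes)}
        h = nx.relabel_nodes(g, mapping)
        a = shortest_path(g, _region(nodes[0]), _region(nodes[-1])).total_length
        b = shortest_path(
            h, _region(mapping[nodes[0]]), _region(mapping[nodes[-1]])
        ).total_length
        assert a == pytest.approx(b, abs=1e-12)


class TestAveragePathLength:
    def test_constant_and_mean(self):
        from fluctnet.pathways import PathResult

        def pr(length):
            return PathResult(("a", "b"), (length,), length, family="VSD-SF")

        assert average_path_length([pr(1.0)] * 4) == 1.0
        assert average_path_length([pr(l) for l in (0.8, 1.0, 1.0, 1.2)]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_path_length([])

    def test_mixed_families_rejected(self):
        from fluctnet.pathways import PathResult

        a = PathResult(("a",), (), 0.0, family="VSD-SF")
        b = PathResult(("a",), (), 0.0, family="PD-SF")
        with pytest.raises(ValueError):
            average_path_length([a, b])


class TestBetweenness:
    def test_single_path_middle_node(self):
        g = nx.Graph()
        g.add_edge("s", "b", weight=1.0)
        g.add_edge("b", "t", weight=1.0)
        b = betweenness(g, [_region("s")], [_region("t")])
        assert b["b"] == pytest.approx(1.0)
        assert b["s"] == b["t"] == 0.0

    def test_two_equal_paths_split_half(self):
        g = nx.Graph()
        for u, v in [("s", "b"), ("b", "t"), ("s", "c"), ("c", "t")]:
            g.add_edge(u, v, weight=1.0)
        g.add_edge("s", "x", weight=5.0)  # off-path decoy
        g.add_edge("x", "t", weight=5.0)
        b = betweenness(g, [_region("s")], [_region("t")])
        assert b["b"] == pytest.approx(0.5)
        assert b["c"] == pytest.approx(0.5)
        assert b["x"] == 0.0

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(31415)
        for _ in range(200):
            g = random_weighted_graph(rng)
            nodes = sorted(g.nodes)
            srcs, tgts = nodes[:2], nodes[-2:]
            expect = brute_betweenness(g, srcs, tgts)
            got = betweenness(g, [_region(*srcs)], [_region(*tgts)])
            for v in g.nodes:
                assert got[v] == pytest.approx(expect[v], abs=1e-9)


class TestCentralityIndex:
    def test_all_paths_through_node(self):
        g = nx.Graph()
        g.add_edge("s", "b", weight=1.0)
        g.add_edge("b", "t", weight=1.0)
        ci = centrality_index(g, _region("s"), _region("t"))
        assert ci["b"] == 1.0

    def test_far_second_path_excluded_by_slack(self):
        g = nx.Graph()
        g.add_edge("s", "b", weight=0.5)
        g.add_edge("b", "t", weight=0.5)
        g.add_edge("s", "c", weight=2.0)
        g.add_edge("c", "t", weight=2.0)  # 4.0 > 1.0 + epsilon
        ci = centrality_index(g, _region("s"), _region("t"), epsilon=1.0)
        assert ci["b"] == 1.0
        assert ci["c"] == 0.0

    def test_two_disjoint_equal_paths_split(self):
        g = nx.Graph()
        for u, v in [("s", "b"), ("b", "t"), ("s", "c"), ("c", "t")]:
            g.add_edge(u, v, weight=1.0)
        ci = centrality_index(g, _region("s"), _region("t"))
        assert ci["b"] == pytest.approx(0.5)
        assert ci["c"] == pytest.approx(0.5)

    def test_k_max_cap_warns(self):
        g = nx.Graph()
        # dense graph with many near-optimal alternatives
        for i in range(8):
            for j in range(i + 1, 8):
                g.add_edge(f"n{i}", f"n{j}", weight=0.01)
        with pytest.warns(UserWarning, match="k_max"):
            centrality_index(g, _region("n0"), _region("n7"), epsilon=5.0, k_max=5)

    def test_matches_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            g = random_weighted_graph(rng, max_nodes=7)
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            eps = 0.5
            lengths = []
            for p in nx.all_simple_paths(g, s, t):
                lengths.append(
                    (sum(g[u][v]["weight"] for u, v in zip(p[:-1], p[1:])), tuple(p))
                )
            best = min(l for l, _ in lengths)
            near = [p for l, p in lengths if l <= best + eps + 1e-12]
            ci = centrality_index(g, _region(s), _region(t), epsilon=eps, k_max=10_000)
            for v in g.nodes:
                expect = sum(1 for p in near if v in p) / len(near)
                assert ci[v] == pytest.approx(expect, abs=1e-9)


class TestRegions:
    @pytest.fixture(scope="class")
    def traj(self, topo):
        return sample_frames(topo, SyntheticSpec(n_frames=200, seed=55))

    def test_anchor_always_member(self, traj):
        r = define_region(traj, "A:1", radius=4.2)
        assert "A:1" in r.members

    def test_unknown_anchor(self, traj):
        with pytest.raises(ResidueLookupError):
            define_region(traj, "Z:1")

    def test_coincident_residue_is_member(self):
        from fluctnet.synthetic import scripted_contact_fixture

        traj, _ = scripted_contact_fixture([1.0], n_frames=100)
        r = define_region(traj, "A:1", radius=6.0)
        assert "A:2" in r.members  # 3 Å away in every frame

    def test_fixed_outside_radius_is_not_member(self):
        from fluctnet.synthetic import scripted_contact_fixture

        traj, _ = scripted_contact_fixture([0.0], n_frames=100)
        # out-of-contact pair sits at cutoff + 3 = 8 Å
        r = define_region(traj, "A:1", radius=6.0)
        assert "A:2" not in r.members

    def test_occupancy_counting(self):
        """Inside the sphere 80% of frames at 75% occupancy: member."""
        from fluctnet.synthetic import scripted_contact_fixture

        traj, _ = scripted_contact_fixture([0.8, 0.6], n_frames=1000)
        r = define_region(traj, "A:1", radius=6.0, occupancy=0.75)
        assert "A:2" in r.members  # 3 Å in 80% of frames, 8 Å otherwise
        r2 = define_region(traj, "A:3", radius=6.0, occupancy=0.75)
        assert "A:4" not in r2.members  # inside only 60% of frames


class TestBanding:
    @pytest.mark.parametrize(
        "b,expected",
        [(0.5, "low"), (1.0, "low"), (1.01, "medium"), (4.0, "medium"), (4.01, "high")],
    )
    def test_bands(self, b, expected):
        assert band_betweenness(b, b_max=9.0) == expected

    def test_zero_is_low(self):
        assert band_betweenness(0.0, 1.0) == "low"

    def test_exceeding_max_rejected(self):
        with pytest.raises(ValueError):
            band_betweenness(10.0, 9.0)

    @given(st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=100, derandomize=True)
    def test_band_consistent_with_value(self, b):
        band = band_betweenness(b, b_max=100.0)
        assert band == ("low" if b <= 1 else "medium" if b <= 4 else "high")


class _Run:
    def __init__(self, lengths, settings=None):
        self.settings = settings or {"cutoff": 5.0}
        self.average_lengths = lengths


class TestCompareRuns:
    def test_hindered_at_two_units(self):
        rep = compare_runs(_Run({"VSD-SF": 1.0}), _Run({"VSD-SF": 3.0}))
        assert rep["VSD-SF"]["flag"] == "hindered"
        assert rep["VSD-SF"]["ratio"] == pytest.approx(math.e**2)

    def test_identity_is_comparable(self):
        rep = compare_runs(_Run({"VSD-SF": 1.0}), _Run({"VSD-SF": 1.0}))
        assert rep["VSD-SF"]["flag"] == "comparable"
        assert rep["VSD-SF"]["ratio"] == 1.0

    def test_enhanced_below_threshold(self):
        rep = compare_runs(_Run({"VSD-SF": 0.97}), _Run({"VSD-SF": 0.62}))
        assert rep["VSD-SF"]["flag"] == "enhanced"

    def test_mismatched_settings_rejected(self):
        with pytest.raises(ComparisonError):
            compare_runs(
                _Run({"VSD-SF": 1.0}, {"cutoff": 5.0}),
                _Run({"VSD-SF": 1.0}, {"cutoff": 4.5}),
            )
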