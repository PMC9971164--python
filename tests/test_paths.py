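import itertools

import networkx as nx
import numpy as np
import pytest

from hergnet.network import WeightMatrix
from hergnet.paths import (
    CouplingGraph,
    NoPath,
    betweenness,
    build_graph,
    compare_paths,
    correlate_metric_vs_energy,
    minimal_path_length,
    shortest_path,
)
from hergnet.trajectory import ResidueRegion


# ---------------------------------------------------------------- oracles

def brute_force_shortest(G, sources, targets):
    """Enumerate every simple path between all (s, t) pairs."""
    best = None
    for s in sources:
        for t in targets:
            if s == t:
                return [s], 0.0
            if s not in G or t not in G:
                continue
            for p in nx.all_simple_paths(G, s, t):
                length = sum(G[u][v]["weight"] for u, v in zip(p, p[1:]))
                if best is None or length < best[1]:
                    best = (p, length)
    return best


def brute_force_betweenness(G):
    """Naive all-pairs shortest-path counting, endpoints excluded."""
    bc = {v: 0.0 for v in G}
    nodes = sorted(G)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        best = None
        if not nx.has_path(G, s, t):
            continue
        for p in nx.all_simple_paths(G, s, t):
            length = sum(G[u][v]["weight"] for u, v in zip(p, p[1:]))
            if best is None or length < best:
                best = length
                paths = [p]
            elif length == best:
                paths.append(p)
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    return bc


def random_int_weight_graph(rng, max_nodes=8):
    """Random connected-ish graph with small integer weights (exact sums)."""
    n = rng.integers(3, max_nodes + 1)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.55:
            G.add_edge(i, j, weight=float(rng.integers(1, 10)))
    return G


def graph_with_regions(edges, regions):
    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=float(w))
    region_map = {
        name: ResidueRegion(name, frozenset(members))
        for name, members in regions.items()
    }
    return CouplingGraph(graph=G, region_map=region_map)


# ---------------------------------------------------------------- tests

class TestBuildGraph:
    def test_toy_matrix_nodes_and_edges(self):
        W = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        mask = W > 0
        cg = build_graph(WeightMatrix(W=W, edge_mask=mask))
        assert set(cg.graph.nodes) == {0, 1, 2}
        assert set(cg.graph.edges) == {(0, 1), (0, 2)}

    def test_empty_mask_gives_unreachable_queries(self):
        W = np.zeros((3, 3))
        cg = build_graph(WeightMatrix(W=W, edge_mask=np.zeros((3, 3), bool)))
        res = shortest_path(cg, {0}, {2})
        assert isinstance(res, NoPath)
        assert not res.reachable

    def test_counts_match_matrix_structure(self, rng):
        n = 6
        M = rng.uniform(0, 2, (n, n))
        M = (M + M.T) / 2
        mask = M > 1.0
        np.fill_diagonal(mask, False)
        cg = build_graph(WeightMatrix(W=M, edge_mask=mask))
        assert cg.graph.number_of_edges() == int(np.triu(mask, 1).sum())
        assert cg.graph.number_of_nodes() == n

    def test_region_referencing_missing_residue_fails(self):
        W = WeightMatrix(W=np.zeros((2, 2)), edge_mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="missing"):
            build_graph(
                W,
                nodes=[("A", 1), ("A", 2)],
                regions=[ResidueRegion("S4", frozenset({("A", 99)}))],
            )

    def test_negative_weight_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=-1.0)
        with pytest.raises(ValueError, match="non-negative"):
            CouplingGraph(graph=G)


class TestShortestPath:
    def test_four_node_example(self):
        G = nx.Graph()
        for u, v, w in [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 3.0), (3, 4, 1.0)]:
            G.add_edge(u, v, weight=w)
        res = shortest_path(CouplingGraph(graph=G), {1}, {4})
        oracle_path, oracle_len = brute_force_shortest(G, {1}, {4})
        assert res.nodes == [1, 2, 3, 4] == oracle_path
        assert res.length == pytest.approx(3.0) and oracle_len == 3.0

    def test_single_edge(self):
        G = nx.Graph()
        G.add_edge("s", "t", weight=2.5)
        res = shortest_path(CouplingGraph(graph=G), {"s"}, {"t"})
        assert res.nodes == ["s", "t"]
        assert res.length == 2.5

    def test_overlapping_sets_degenerate_zero_path(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        res = shortest_path(CouplingGraph(graph=G), {0, 1}, {1, 2}.union({1}))
        assert res.length == 0.0
        assert res.nodes == [1]

    def test_tie_break_prefers_fewer_hops(self):
        G = nx.Graph()
        G.add_edge(0, 3, weight=2.0)  # direct, 1 hop
        G.add_edge(0, 1, weight=1.0)
        G.add_edge(1, 3, weight=1.0)  # same length, 2 hops
        res = shortest_path(CouplingGraph(graph=G), {0}, {3})
        assert res.nodes == [0, 3]

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            G = random_int_weight_graph(rng)
            nodes = sorted(G)
            sources = {nodes[0]}
            targets = {nodes[-1]}
            res = shortest_path(CouplingGraph(graph=G), sources, targets)
            oracle = brute_force_shortest(G, sources, targets)
            if oracle is None:
                assert isinstance(res, NoPath)
            else:
                assert res.length == oracle[1]

    def test_length_equals_sum_of_traversed_weights(self):
        rng = np.random.default_rng(5)
        G = random_int_weight_graph(rng)
        res = shortest_path(CouplingGraph(graph=G), {0}, {max(G.nodes)})
        if res.reachable:
            total = sum(
                G[u][v]["weight"] for u, v in zip(res.nodes, res.nodes[1:])
            )
            assert abs(res.length - total) < 1e-9


class TestMinimalPathLength:
    def _four_subunit_graph(self, scale=1.0):
        edges = []
        regions = {"S4": set(), "S6": set()}
        for chain in "ABCD":
            edges += [
                ((chain, 1), (chain, 2), 1.0 * scale),
                ((chain, 2), (chain, 3), 2.0 * scale),
            ]
            regions["S4"].add((chain, 1))
            regions["S6"].add((chain, 3))
        return graph_with_regions(edges, regions)

    def test_four_identical_subunits_give_identical_dmin(self):
        cg = self._four_subunit_graph()
        res = minimal_path_length(cg, "S4", "S6")
        lengths = {chain: p.length for chain, p in res.items()}
        assert set(lengths) == set("ABCD")
        assert len(set(lengths.values())) == 1
        assert lengths["A"] == pytest.approx(3.0)

    def test_weight_scaling_scales_dmin_not_path(self):
        base = self._four_subunit_graph(1.0)
        scaled = self._four_subunit_graph(2.5)
        r1 = minimal_path_length(base, "S4", "S6")["A"]
        r2 = minimal_path_length(scaled, "S4", "S6")["A"]
        assert r2.nodes == r1.nodes
        assert r2.length == pytest.approx(2.5 * r1.length)

    def test_global_mode_returns_single_minimum(self):
        cg = self._four_subunit_graph()
        res = minimal_path_length(cg, "S4", "S6", per_subunit=False)
        assert res.length == pytest.approx(3.0)

    def test_triangle_inequality_over_regions(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            G = random_int_weight_graph(rng)
            nodes = sorted(G)
            if len(nodes) < 3:
                continue
            a, b, c = nodes[0], nodes[len(nodes) // 2], nodes[-1]
            cg = CouplingGraph(graph=G)
            ab = shortest_path(cg, {a}, {b})
            bc = shortest_path(cg, {b}, {c})
            ac = shortest_path(cg, {a}, {c})
            if ab.reachable and bc.reachable and ac.reachable:
                assert ac.length <= ab.length + bc.length + 1e-9


class TestBetweenness:
    def test_five_node_path_graph(self):
        G = nx.path_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        prof = betweenness(CouplingGraph(graph=G), normalized=False)
        assert prof.bc[2] == pytest.approx(4.0)
        assert prof.bc[1] == pytest.approx(3.0)
        assert prof.bc[0] == 0.0 and prof.bc[4] == 0.0

    def test_star_center_normalized_is_one(self):
        G = nx.star_graph(6)
        nx.set_edge_attributes(G, 1.0, "weight")
        prof = betweenness(CouplingGraph(graph=G), normalized=True)
        assert prof.bc[0] == pytest.approx(1.0)

    def test_isolated_node_is_zero(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_node(2)
        prof = betweenness(CouplingGraph(graph=G))
        assert prof.bc[2] == 0.0

    def test_matches_naive_counting_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            G = random_int_weight_graph(rng, max_nodes=7)
            prof = betweenness(CouplingGraph(graph=G), normalized=False)
            oracle = brute_force_betweenness(G)
            for v in G:
                assert prof.bc[v] == pytest.approx(oracle[v], abs=1e-9)


class TestComparePaths:
    def _wt(self):
        edges = [
            (("A", 1), ("A", 2), 1.0),
            (("A", 2), ("A", 3), 1.0),
            (("A", 1), ("A", 3), 5.0),
        ]
        return graph_with_regions(
            edges, {"S4": {("A", 1)}, "S6": {("A", 3)}}
        )

    def test_identical_graphs_give_zero_delta(self):
        wt = self._wt()
        cmp = compare_paths(wt, self._wt(), "S4", "S6")
        assert cmp.delta_mean == 0.0
        assert cmp.delta_sd == 0.0

    def test_on_path_weight_increase_raises_delta(self):
        wt = self._wt()
        mut = self._wt()
        mut.graph[("A", 1)][("A", 2)]["weight"] = 2.5
        cmp = compare_paths(wt, mut, "S4", "S6")
        assert cmp.delta_mean > 0.0

    def test_delta_matches_brute_force_recomputation(self):
        wt = self._wt()
        mut = self._wt()
        for u, v in mut.graph.edges:
            mut.graph[u][v]["weight"] *= 1.7
        cmp = compare_paths(wt, mut, "S4", "S6")
        o_wt = brute_force_shortest(wt.graph, {("A", 1)}, {("A", 3)})
        o_mut = brute_force_shortest(mut.graph, {("A", 1)}, {("A", 3)})
        assert cmp.delta_mean == pytest.approx(o_mut[1] - o_wt[1], abs=1e-12)

    def test_region_mismatch_raises(self):
        wt = self._wt()
        mut = graph_with_regions(
            [(("A", 1), ("A", 2), 1.0)], {"S4": {("A", 1)}}
        )
        with pytest.raises(ValueError, match="region"):
            compare_paths(wt, mut, "S4", "S6")


class TestCorrelation:
    def test_exact_line(self):
        xs = np.arange(1.0, 9.0)
        rep = correlate_metric_vs_energy(xs, 2.0 * xs + 1.0)
        assert rep.r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(1.0)
        assert rep.n == 8

    def test_anticorrelation(self):
        xs = np.arange(5.0)
        rep = correlate_metric_vs_energy(xs, -xs)
        assert rep.r == pytest.approx(-1.0)

    def test_hand_table_matches_textbook_formula(self):
        xs = np.array([0.1, 0.5, 0.9, 1.3, 2.0, 2.2, 3.1, 4.0])
        ys = np.array([0.2, 0.3, 1.1, 0.9, 2.5, 1.8, 3.3, 3.9])
        rep = correlate_metric_vs_energy(xs, ys)
        # independent closed-form Pearson r
        n = len(xs)
        num = n * (xs * ys).sum() - xs.sum() * ys.sum()
        den = np.sqrt(n * (xs**2).sum() - xs.sum() ** 2) * np.sqrt(
            n * (ys**2).sum() - ys.sum() ** 2
        )
        assert rep.r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_metric_vs_energy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="3 points"):
            correlate_metric_vs_energy([1.0, 2.0], [1.0, 2.0])
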