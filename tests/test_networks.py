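import io
import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import misinfogame as mg
from misinfogame.networks import (
    EdgeListParseError,
    EmptyEdgeListError,
    GraphSpecError,
    NetworkSpec,
)


class TestLattice:
    @pytest.mark.parametrize(
        "rows,cols,nbhd,periodic,n,m,k",
        [
            (30, 30, "von_neumann", True, 900, 1800, 4),
            (30, 30, "moore", True, 900, 3600, 8),
            (5, 4, "von_neumann", True, 20, 40, 4),
        ],
    )
    def test_regular_cases(self, rows, cols, nbhd, periodic, n, m, k):
        g = mg.make_lattice(rows, cols, nbhd, periodic)
        assert g.n == n and g.num_edges == m
        assert g.is_regular and g.k == k
        g.validate()

    def test_open_boundary_degrees(self):
        g = mg.make_lattice(3, 3, periodic=False)
        deg = g.degrees
        assert deg[0] == deg[2] == deg[6] == deg[8] == 2  # corners
        assert deg[4] == 4  # center

    def test_node_indexing_row_major(self):
        g = mg.make_lattice(4, 5, periodic=False)
        # node (r=1, c=2) -> 7; its von Neumann neighbors
        assert set(g.neighbors(1 * 5 + 2).tolist()) == {2, 6, 8, 12}

    @pytest.mark.parametrize("rows,cols,periodic", [(0, 5, False), (5, -1, False), (2, 5, True)])
    def test_invalid_spec(self, rows, cols, periodic):
        with pytest.raises(GraphSpecError):
            mg.make_lattice(rows, cols, periodic=periodic)

    def test_periodic_lattice_vertex_transitive(self):
        g = mg.make_lattice(8, 8)
        assert (g.degrees == 4).all()
        btw = mg.betweenness_scores(g)
        assert np.allclose(btw, btw[0])


class TestSmallWorld:
    def test_ring_limit(self):
        sw = mg.make_small_world(900, 8, 0.0, seed=0)
        assert sw.n_rewired == 0
        assert sw.graph.num_edges == 3600
        assert sw.graph.is_regular and sw.graph.k == 8
        # ring-lattice clustering coefficient 3(k-2) / (4(k-1))
        cc = nx.average_clustering(mg.make_small_world(100, 8, 0.0, seed=0).graph.to_networkx())
        assert cc == pytest.approx(3 * 6 / (4 * 7))

    def test_shortcut_count_mean_matches_binomial(self):
        n, k, p, seeds = 200, 6, 0.05, 1000
        counts = [mg.make_small_world(n, k, p, seed=s).n_rewired for s in range(seeds)]
        expected = n * k * p
        se = np.sqrt(n * k * p * (1 - p) / seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_one_pass_convention_half_rate(self):
        n, k, p, seeds = 200, 6, 0.05, 500
        counts = [
            mg.make_small_world(n, k, p, seed=s, convention="one_pass").n_rewired
            for s in range(seeds)
        ]
        expected = n * k * p / 2
        se = np.sqrt(n * k / 2 * p * (1 - p) / seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_full_rewire_stays_simple(self):
        sw = mg.make_small_world(10, 4, 1.0, seed=3)
        sw.graph.validate()
        assert sw.graph.degrees.sum() == 40

    def test_odd_degree_rejected(self):
        with pytest.raises(GraphSpecError):
            mg.make_small_world(100, 5, 0.1)

    @given(
        n=st.integers(min_value=10, max_value=60),
        half=st.integers(min_value=1, max_value=3),
        p=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_generated_graphs_stay_simple_and_balanced(self, n, half, p, seed):
        k = 2 * half
        sw = mg.make_small_world(n, k, p, seed=seed)
        sw.graph.validate()  # symmetry, no self-loops, sorted adjacency
        assert sw.graph.degrees.sum() == n * k


class TestEdgeList:
    def test_symmetrize_and_dedupe(self):
        g, id_map = mg.read_edge_list(io.StringIO("0 1\n1 0\n1 2\n"))
        assert g.n == 3 and g.num_edges == 2
        assert set(g.neighbors(1).tolist()) == {0, 2}

    def test_comment_and_remap(self):
        g, id_map = mg.read_edge_list(io.StringIO("# comment\n5 9\n"))
        assert g.n == 2 and g.num_edges == 1
        assert id_map == {5: 0, 9: 1}

    def test_self_loop_dropped(self):
        g, _ = mg.read_edge_list(io.StringIO("3 3\n"))
        assert g.n == 1 and g.num_edges == 0

    def test_parse_error_names_line(self):
        with pytest.raises(EdgeListParseError, match="line 2"):
            mg.read_edge_list(io.StringIO("1 2\nfoo bar\n"))

    def test_empty_stream_rejected(self):
        with pytest.raises(EmptyEdgeListError):
            mg.read_edge_list(io.StringIO("# nothing here\n"))

    def test_round_trip(self):
        g = mg.make_small_world(60, 6, 0.2, seed=9).graph
        buf = io.StringIO()
        mg.write_edge_list(g, buf)
        buf.seek(0)
        g2, _ = mg.read_edge_list(buf)
        assert np.array_equal(g.indptr, g2.indptr)
        assert np.array_equal(g.indices, g2.indices)


def _brute_force_betweenness(g: mg.Graph) -> np.ndarray:
    """Floyd–Warshall shortest-path counting, independent of Brandes."""
    n = g.n
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for i in range(n):
        dist[i, i] = 0
        sigma[i, i] = 1
    for u in range(n):
        for v in g.neighbors(u):
            dist[u, v] = 1
            sigma[u, v] = 1
    for m in range(n):
        for s in range(n):
            for t in range(n):
                d = dist[s, m] + dist[m, t]
                if d < dist[s, t]:
                    dist[s, t] = d
                    sigma[s, t] = sigma[s, m] * sigma[m, t]
                elif d == dist[s, t] and m not in (s, t) and np.isfinite(d):
                    sigma[s, t] += sigma[s, m] * sigma[m, t]
    # recompute sigma cleanly by BFS layers to avoid double counting
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            sigma[s, t] = sum(
                sigma[s, u] for u in g.neighbors(t) if dist[s, u] == dist[s, t] - 1
            )
    btw = np.zeros(n)
    for v in range(n):
        for s, t in itertools.combinations(range(n), 2):
            if v in (s, t) or not np.isfinite(dist[s, t]):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


class TestScores:
    def test_degree_star_and_lattice(self):
        star = mg.Graph.from_edges(5, [(0, i) for i in range(1, 5)])
        assert mg.degree_scores(star).tolist() == [4, 1, 1, 1, 1]
        lat = mg.make_lattice(30, 30)
        assert (mg.degree_scores(lat) == 4).all()
        empty = mg.Graph.from_edges(3, [])
        assert (mg.degree_scores(empty) == 0).all()

    def test_betweenness_path_and_cycle(self):
        path = mg.Graph.from_edges(3, [(0, 1), (1, 2)])
        assert mg.betweenness_scores(path).tolist() == [0.0, 1.0, 0.0]
        cyc = mg.Graph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        btw = mg.betweenness_scores(cyc)
        assert np.allclose(btw, btw[0])

    def test_betweenness_matches_brute_force(self):
        gnx = nx.gnp_random_graph(12, 0.3, seed=4)
        g = mg.Graph.from_edges(12, list(gnx.edges()))
        assert np.allclose(mg.betweenness_scores(g), _brute_force_betweenness(g))

    def test_sampled_with_all_sources_equals_exact(self):
        gnx = nx.gnp_random_graph(50, 0.1, seed=7)
        g = mg.Graph.from_edges(50, list(gnx.edges()))
        exact = mg.betweenness_scores(g)
        sampled = mg.betweenness_scores(g, sample_sources=50, seed=1)
        assert np.allclose(exact, sampled)

    def test_oversampling_clamped_with_warning(self):
        g = mg.Graph.from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        with pytest.warns(UserWarning, match="clamped"):
            scores = mg.betweenness_scores(g, sample_sources=10, seed=0)
        assert np.allclose(scores, mg.betweenness_scores(g))


class TestComponents:
    def test_block_subset_single_component(self):
        g = mg.make_lattice(5, 5)
        block = [0, 1, 5, 6]  # a 2x2 block
        comps = mg.components(g, block)
        assert len(comps) == 1 and sorted(comps[0].tolist()) == block

    def test_diagonal_nodes_are_singletons(self):
        g = mg.make_lattice(5, 5)
        comps = mg.components(g, [0, 6])
        assert [len(c) for c in comps] == [1, 1]

    def test_full_connected_graph_one_component(self):
        g = mg.make_lattice(4, 4)
        comps = mg.components(g)
        assert len(comps) == 1 and len(comps[0]) == 16

    def test_ordering_by_size_then_smallest_member(self):
        g = mg.Graph.from_edges(6, [(0, 1), (2, 3), (4, 5)])
        comps = mg.components(g, [0, 1, 2, 3, 4, 5])
        assert [c[0] for c in comps] == [0, 2, 4]


class TestNetworkSpec:
    def test_build_families(self, tmp_path):
        assert NetworkSpec().build().n == 900
        assert NetworkSpec(family="small_world", n=50, base_degree=4).build(seed=1).n == 50
        p = tmp_path / "edges.txt"
        p.write_text("0 1\n1 2\n")
        assert NetworkSpec(family="edge_list", path=str(p)).build().num_edges == 2

    def test_invalid_small_world_spec(self):
        with pytest.raises(GraphSpecError):
            NetworkSpec(family="small_world", n=10, base_degree=3)
        with pytest.raises(GraphSpecError):
            NetworkSpec(family="small_world", n=10, base_degree=4, rewire_prob=1.5)
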