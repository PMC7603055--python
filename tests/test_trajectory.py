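import networkx as nx
import numpy as np
import pytest

from somscape import (
    Portrait,
    SOMGrid,
    build_capacity_graph,
    kmeans_segment,
    max_capacity_path,
    max_sum_path,
    topographic_path,
    trajectory_profile,
)
from somscape.simulate import generate_toy_graph


def _enumerate_best(g, source, sink, mode):
    """Brute-force oracle over all simple paths."""
    best_key, best_path = None, None
    for path in nx.all_simple_paths(g, source, sink):
        caps = [g[a][b]["capacity"] for a, b in zip(path, path[1:])]
        if mode == "widest":
            key = (min(caps), sum(caps))
        else:
            key = (sum(caps), min(caps))
        if best_key is None or key > best_key:
            best_key, best_path = key, path
    return best_key, best_path


class TestCapacityGraph:
    def test_uniform_portrait_gives_equal_capacities(self, small_model):
        seg = kmeans_segment(small_model, k=6, seed=0)
        p = Portrait(
            grid=small_model.grid,
            values=np.full(small_model.grid.n_nodes, 2.5),
            subject="uniform",
        )
        g = build_capacity_graph(seg, p)
        caps = {round(d["capacity"], 12) for _, _, d in g.edges(data=True)}
        assert caps == {2.5 + 2.5 - 2 * 2.5}  # all zero after the shift

    def test_capacity_arithmetic_with_known_means(self):
        # two clusters, means 2 and 3, min mean 2 -> capacity 2+3-4 = 1
        from somscape.segmentation import ModuleSegmentation, cluster_adjacency

        grid = SOMGrid(2, 2)
        labels = np.array([0, 0, 1, 1])
        seg = ModuleSegmentation(grid=grid, labels=labels, letters={0: "A", 1: "B"})
        seg.adjacency = cluster_adjacency(seg, grid)
        p = Portrait(grid=grid, values=np.array([2.0, 2.0, 3.0, 3.0]), subject="x")
        g = build_capacity_graph(seg, p)
        assert g["A"]["B"]["capacity"] == pytest.approx(1.0)

    def test_capacities_match_independent_cluster_means(self, small_model):
        seg = kmeans_segment(small_model, k=8, seed=0)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=small_model.grid.n_nodes)
        p = Portrait(grid=small_model.grid, values=vals, subject="r")
        g = build_capacity_graph(seg, p)
        means = {c: vals[seg.labels == c].mean() for c in np.unique(seg.labels)}
        shift = min(means.values())
        for c1, c2 in seg.adjacency.edges:
            got = g[seg.letters[c1]][seg.letters[c2]]["capacity"]
            assert got == pytest.approx(means[c1] + means[c2] - 2 * shift)
        assert min(d["capacity"] for _, _, d in g.edges(data=True)) >= 0

    def test_grid_mismatch_rejected(self, small_model):
        seg = kmeans_segment(small_model, k=4, seed=0)
        p = Portrait(grid=SOMGrid(4, 4), values=np.zeros(16), subject="x")
        with pytest.raises(ValueError, match="grid"):
            build_capacity_graph(seg, p)


class TestWidestPath:
    def test_chain_fixture(self):
        g = generate_toy_graph("chain", {"caps": [5.0, 3.0]})
        traj = max_capacity_path(g, "S", "T")
        assert traj.path == ["S", "X1", "T"]
        assert traj.score == pytest.approx(3.0)

    def test_diamond_prefers_wider_route(self):
        g = generate_toy_graph("diamond", {"caps": [2.0, 5.0, 4.0, 3.0]})
        traj = max_capacity_path(g, "S", "T")
        assert traj.path == ["S", "B", "T"]
        assert traj.score == pytest.approx(3.0)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        for seed in range(100):
            g = generate_toy_graph("random", {"n": 8, "p": 0.45}, seed=seed)
            nodes = sorted(g)
            src, snk = nodes[0], nodes[-1]
            (bottleneck, _), _ = _enumerate_best(g, src, snk, "widest"), None
            traj = max_capacity_path(g, src, snk)
            assert traj.score == pytest.approx(bottleneck[0])
            caps = [g[a][b]["capacity"] for a, b in zip(traj.path, traj.path[1:])]
            assert min(caps) == pytest.approx(bottleneck[0])
            assert sum(caps) == pytest.approx(bottleneck[1])

    def test_bottleneck_equals_min_cut_bottleneck(self):
        # widest-path bottleneck == max over paths of min capacity ==
        # the largest c such that source and sink stay connected using
        # only edges of capacity >= c (threshold/min-cut duality)
        for seed in range(30):
            g = generate_toy_graph("random", {"n": 9, "p": 0.4}, seed=seed + 500)
            nodes = sorted(g)
            src, snk = nodes[0], nodes[-1]
            traj = max_capacity_path(g, src, snk)
            feasible = []
            for c in sorted({d["capacity"] for _, _, d in g.edges(data=True)}):
                sub = nx.Graph(
                    [(u, v) for u, v, d in g.edges(data=True) if d["capacity"] >= c]
                )
                if sub.has_node(src) and sub.has_node(snk) and nx.has_path(sub, src, snk):
                    feasible.append(c)
            assert traj.score == pytest.approx(max(feasible))

    def test_disconnected_endpoints_named_in_error(self):
        g = nx.Graph()
        g.add_edge("A", "B", capacity=1.0)
        g.add_node("Z")
        with pytest.raises(ValueError, match="A.*Z|Z.*A"):
            max_capacity_path(g, "A", "Z")

    def test_source_equal_sink_rejected(self):
        g = generate_toy_graph("chain", {"caps": [1.0]})
        with pytest.raises(ValueError, match="differ"):
            max_capacity_path(g, "S", "S")


class TestMaxSumPath:
    def test_chain_is_unique_path(self):
        g = generate_toy_graph("chain", {"caps": [5.0, 3.0]})
        traj = max_sum_path(g, "S", "T")
        assert traj.path == ["S", "X1", "T"]
        assert traj.score == pytest.approx(8.0)

    def test_diamond_tie_broken_by_bottleneck(self):
        # both routes sum to 7; S-B-T has bottleneck 3 > 2
        g = generate_toy_graph("diamond", {"caps": [2.0, 5.0, 4.0, 3.0]})
        traj = max_sum_path(g, "S", "T")
        assert traj.path == ["S", "B", "T"]
        assert traj.score == pytest.approx(7.0)

    def test_matches_exhaustive_enumeration(self):
        for seed in range(100):
            g = generate_toy_graph("random", {"n": 8, "p": 0.45}, seed=seed + 1000)
            nodes = sorted(g)
            src, snk = nodes[0], nodes[-1]
            (best, _), _ = _enumerate_best(g, src, snk, "sum"), None
            traj = max_sum_path(g, src, snk)
            assert traj.score == pytest.approx(best[0])

    def test_node_budget_enforced(self):
        g = nx.complete_graph(12)
        nx.set_edge_attributes(g, 1.0, "capacity")
        with pytest.raises(ValueError, match="max_capacity_path"):
            max_sum_path(g, 0, 1, node_budget=10)


class TestTopographicPath:
    def test_source_equals_sink(self):
        p = generate_toy_graph("grid", {"rows": 5, "cols": 5})
        traj = topographic_path(p, 7, 7)
        assert traj.path == [7] and traj.score == 0.0

    def test_flat_grid_corner_to_corner_closed_form(self):
        grid = SOMGrid(3, 3)
        c = 2.0
        p = Portrait(grid=grid, values=np.full(9, c), subject="flat")
        traj = topographic_path(p, 0, 8)
        # rescaled height is eps everywhere... plus the floor; two diagonal steps
        eps = 1e-6
        assert traj.score == pytest.approx(2 * np.sqrt(2) * eps)
        assert len(traj.path) == 3

    def test_shift_invariance_after_rescaling(self):
        rng = np.random.default_rng(2)
        grid = SOMGrid(6, 6)
        vals = rng.normal(size=36)
        t1 = topographic_path(Portrait(grid=grid, values=vals, subject="a"), 0, 35)
        t2 = topographic_path(
            Portrait(grid=grid, values=vals + 17.3, subject="b"), 0, 35
        )
        assert t1.path == t2.path
        assert t1.score == pytest.approx(t2.score)

    def test_planted_valley_is_followed(self):
        p = generate_toy_graph(
            "grid", {"rows": 5, "cols": 5, "valley": [(r, 2) for r in range(5)]}
        )
        grid = p.grid
        traj = topographic_path(p, grid.node_index(0, 2), grid.node_index(4, 2))
        assert traj.path == [grid.node_index(r, 2) for r in range(5)]

    @pytest.mark.parametrize("rows,cols", [(5, 5), (8, 6), (10, 10)])
    def test_matches_networkx_dijkstra_on_explicit_edge_list(self, rows, cols):
        rng = np.random.default_rng(rows * 100 + cols)
        grid = SOMGrid(rows, cols)
        vals = rng.uniform(0, 3, grid.n_nodes)
        p = Portrait(grid=grid, values=vals, subject="r")
        src, snk = 0, grid.n_nodes - 1
        traj = topographic_path(p, src, snk)
        # independent oracle: explicit edge list + networkx Dijkstra
        h = vals - vals.min() + 1e-6
        og = nx.Graph()
        for node in range(grid.n_nodes):
            r, c = grid.node_coord(node)
            for nb in grid.neighbors8(node):
                nr, nc = grid.node_coord(nb)
                w = np.hypot(nr - r, nc - c) * (h[node] + h[nb]) / 2
                og.add_edge(node, nb, weight=w)
        expected = nx.dijkstra_path_length(og, src, snk)
        assert traj.score == pytest.approx(expected, rel=1e-10)


class TestTrajectoryProfile:
    def test_single_node_path_row_equals_node_values(self):
        grid = SOMGrid(3, 3)
        ports = [
            Portrait(grid=grid, values=np.arange(9, dtype=float) * (t + 1), subject=str(t))
            for t in range(3)
        ]
        from somscape import GeneStateTrajectory

        traj = GeneStateTrajectory(path=[4], score=0.0, method_tag="topographic")
        prof = trajectory_profile(traj, ports)
        np.testing.assert_allclose(prof, [[4.0, 8.0, 12.0]])

    def test_constant_portraits_give_constant_matrix(self, small_model):
        seg = kmeans_segment(small_model, k=4, seed=0)
        letters = [seg.letters[c] for c in range(2)]
        from somscape import GeneStateTrajectory

        traj = GeneStateTrajectory(path=letters, score=1.0, method_tag="maxflow")
        ports = [
            Portrait(grid=small_model.grid, values=np.full(small_model.grid.n_nodes, 3.3), subject="c")
            for _ in range(4)
        ]
        prof = trajectory_profile(traj, ports, seg)
        np.testing.assert_allclose(prof, 3.3)

    def test_cluster_path_requires_segmentation(self):
        from somscape import GeneStateTrajectory

        grid = SOMGrid(3, 3)
        traj = GeneStateTrajectory(path=["A", "B"], score=1.0, method_tag="maxflow")
        ports = [Portrait(grid=grid, values=np.zeros(9), subject="z")]
        with pytest.raises(ValueError, match="segmentation"):
            trajectory_profile(traj, ports)
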