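"""Gene-state differentiation trajectories on the expression landscape.

A differentiation process appears in the map as a "flow" of overexpression
from the stemness source spot to a tissue sink spot. Two path constructions
summarize it:

* **Capacity paths** run on the cluster adjacency network. Each edge
  between neighboring clusters carries a capacity derived from the two
  clusters' mean signed-log expression in a lineage portrait; the
  trajectory is the source-to-sink path that maximizes either the minimum
  edge capacity (widest / maximum-bottleneck path, the default) or the
  capacity sum (an explicitly exhaustive alternative).
* **Topographic paths** run on the grid itself, treating a difference
  portrait (stem minus tissue) as elevation: Dijkstra's least-cost route
  descends "downhill along valleys" of the landscape, the data-driven
  analogue of a Waddington surface.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .segmentation import ModuleSegmentation
from .som import Portrait, SOMGrid

_TOPO_EPS = 1e-6  # elevation floor; keeps every step strictly positive-cost

METHOD_TAGS = ("maxflow", "sumpath", "topographic", "velocity")


@dataclass
class GeneStateTrajectory:
    """Ordered source-to-sink sequence of clusters or grid nodes."""

    path: list
    score: float
    per_step_expression: list[float] = field(default_factory=list)
    method_tag: str = "maxflow"

    def __post_init__(self) -> None:
        if len(self.path) != len(set(map(str, self.path))):
            raise ValueError("trajectory may not repeat elements")
        if self.method_tag not in METHOD_TAGS:
            raise ValueError(f"method_tag must be one of {METHOD_TAGS}")

    def to_json(self, source=None, sink=None) -> str:
        return json.dumps(
            {
                "method": self.method_tag,
                "source": source if source is not None else self.path[0],
                "sink": sink if sink is not None else self.path[-1],
                "path": list(self.path),
                "score": self.score,
                "per_step_expression": list(self.per_step_expression),
            },
            default=str,
        )


# ---------------------------------------------------------------------------
# capacity network
# ---------------------------------------------------------------------------


def build_capacity_graph(
    seg: ModuleSegmentation, lineage_portrait: Portrait
) -> nx.Graph:
    """Cluster adjacency network weighted by lineage expression.

    For neighboring clusters c1, c2 the edge capacity is
    ``m(c1) + m(c2) - 2 * min_c m(c)`` where ``m(c)`` is the mean of the
    lineage portrait over c's nodes. The shift by twice the minimum
    cluster mean makes all capacities nonnegative (signed-log means can be
    negative) while preserving their ordering. Nodes are cluster letters;
    each carries its mean expression as the ``mean_expression`` attribute.
    """
    if lineage_portrait.grid != seg.grid:
        raise ValueError("portrait and segmentation grids differ")
    clusters = [int(c) for c in np.unique(seg.labels)]
    means = {
        c: float(lineage_portrait.values[seg.labels == c].mean()) for c in clusters
    }
    shift = min(means.values())
    g = nx.Graph()
    for c in clusters:
        g.add_node(seg.letters[c], mean_expression=means[c])
    for c1, c2 in seg.adjacency.edges:
        cap = means[c1] + means[c2] - 2.0 * shift
        g.add_edge(seg.letters[c1], seg.letters[c2], capacity=cap)
    return g


def _check_endpoints(g: nx.Graph, source, sink) -> None:
    if source == sink:
        raise ValueError("source and sink must differ")
    for v in (source, sink):
        if v not in g:
            raise ValueError(f"node {v!r} not in graph")
    if not nx.has_path(g, source, sink):
        raise ValueError(f"source {source!r} and sink {sink!r} are disconnected")


def _per_step_expression(g: nx.Graph, path: list) -> list[float]:
    return [float(g.nodes[v].get("mean_expression", np.nan)) for v in path]


def _widest_bottleneck(g: nx.Graph, source, sink) -> float:
    """Maximum-bottleneck value via max-min Dijkstra relaxation."""
    best = {v: -np.inf for v in g}
    best[source] = np.inf
    heap = [(-np.inf, str(source), source)]
    while heap:
        neg_w, _, u = heapq.heappop(heap)
        w = -neg_w
        if w < best[u]:
            continue
        if u == sink:
            return w
        for v in g[u]:
            cand = min(w, g[u][v]["capacity"])
            if cand > best[v]:
                best[v] = cand
                heapq.heappush(heap, (-cand, str(v), v))
    raise ValueError(f"source {source!r} and sink {sink!r} are disconnected")


class _SearchBudgetExceeded(Exception):
    pass


def _best_sum_path(
    g: nx.Graph,
    source,
    sink,
    min_capacity: float | None = None,
    max_expansions: int | None = None,
) -> tuple[list, float, float]:
    """Max-sum simple path by exhaustive DFS; lexicographic tie-break.

    Neighbors are explored in sorted order, so the first path achieving
    the best (sum, bottleneck) key is the lexicographically smallest;
    strict-improvement updates preserve it. A per-node upper bound (the
    largest incident capacity of every still-reachable node) prunes
    branches that cannot beat the incumbent. ``max_expansions`` caps the
    search on graphs where enumeration is infeasible.
    """
    sub = g
    if min_capacity is not None:
        sub = nx.Graph()
        sub.add_nodes_from(g.nodes(data=True))
        sub.add_edges_from(
            (u, v, d)
            for u, v, d in g.edges(data=True)
            if d["capacity"] >= min_capacity - 1e-12
        )
    # optimistic per-node increment: the best edge that could enter the node
    node_bound = {
        u: max((sub[u][v]["capacity"] for v in sub[u]), default=0.0) for u in sub
    }
    best: dict = {"key": (-np.inf, -np.inf), "path": None}
    order = {u: sorted(sub[u], key=str) for u in sub}
    counter = {"n": 0}

    def dfs(u, visited, acc_sum, acc_bottleneck, path):
        counter["n"] += 1
        if max_expansions is not None and counter["n"] > max_expansions:
            raise _SearchBudgetExceeded
        if u == sink:
            key = (acc_sum, acc_bottleneck)
            if key > best["key"]:
                best["key"] = key
                best["path"] = list(path)
            return
        optimistic = acc_sum + sum(
            b for v, b in node_bound.items() if v not in visited
        ) + node_bound.get(sink, 0.0)
        if optimistic < best["key"][0] - 1e-12:
            return
        for v in order[u]:
            if v in visited:
                continue
            cap = sub[u][v]["capacity"]
            visited.add(v)
            path.append(v)
            dfs(v, visited, acc_sum + cap, min(acc_bottleneck, cap), path)
            path.pop()
            visited.remove(v)

    dfs(source, {source}, 0.0, np.inf, [source])
    if best["path"] is None:
        raise ValueError(f"source {source!r} and sink {sink!r} are disconnected")
    return best["path"], best["key"][0], best["key"][1]


def _widest_dijkstra_path(g: nx.Graph, source, sink) -> tuple[list, float]:
    """Max-min Dijkstra with predecessor tracking (deterministic ties)."""
    best = {v: -np.inf for v in g}
    pred: dict = {source: None}
    best[source] = np.inf
    heap = [(-np.inf, str(source), source)]
    while heap:
        neg_w, _, u = heapq.heappop(heap)
        w = -neg_w
        if w < best[u]:
            continue
        for v in sorted(g[u], key=str):
            cand = min(w, g[u][v]["capacity"])
            if cand > best[v]:
                best[v] = cand
                pred[v] = u
                heapq.heappush(heap, (-cand, str(v), v))
    if best[sink] == -np.inf:
        raise ValueError(f"source {source!r} and sink {sink!r} are disconnected")
    path = [sink]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    path.reverse()
    return path, best[sink]


def max_capacity_path(g: nx.Graph, source, sink) -> GeneStateTrajectory:
    """Widest (maximum-bottleneck) path from source to sink.

    The returned path maximizes the minimum edge capacity; among widest
    paths it has maximal capacity sum, remaining ties broken by
    lexicographic node order. The score is the bottleneck capacity.
    """
    _check_endpoints(g, source, sink)
    bottleneck = _widest_bottleneck(g, source, sink)
    try:
        path, _, _ = _best_sum_path(
            g, source, sink, min_capacity=bottleneck, max_expansions=500_000
        )
    except _SearchBudgetExceeded:
        # enumeration of widest paths infeasible: fall back to the
        # deterministic max-min Dijkstra path (same bottleneck)
        path, _ = _widest_dijkstra_path(g, source, sink)
    return GeneStateTrajectory(
        path=path,
        score=float(bottleneck),
        per_step_expression=_per_step_expression(g, path),
        method_tag="maxflow",
    )


def max_sum_path(g: nx.Graph, source, sink, node_budget: int = 40) -> GeneStateTrajectory:
    """Simple path maximizing total capacity (exhaustive branch-and-bound).

    The underlying problem is a longest-simple-path variant, so the search
    is exponential in the worst case; ``node_budget`` caps the graph size.
    Ties go to the larger bottleneck, then lexicographic node order.
    """
    if g.number_of_nodes() > node_budget:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes, above the exhaustive-search "
            f"budget of {node_budget}; use max_capacity_path instead"
        )
    _check_endpoints(g, source, sink)
    try:
        path, total, _ = _best_sum_path(g, source, sink, max_expansions=5_000_000)
    except _SearchBudgetExceeded:
        raise RuntimeError(
            "exhaustive path search exceeded its budget on this graph; "
            "use max_capacity_path instead"
        ) from None
    return GeneStateTrajectory(
        path=path,
        score=float(total),
        per_step_expression=_per_step_expression(g, path),
        method_tag="sumpath",
    )


# ---------------------------------------------------------------------------
# topographic least-cost path
# ---------------------------------------------------------------------------


def _grid_cost_graph(height: np.ndarray, grid: SOMGrid):
    """Sparse 8-connected cost matrix: step length x mean rescaled elevation."""
    h = height - height.min() + _TOPO_EPS
    rows, cols, data = [], [], []
    for node in range(grid.n_nodes):
        r, c = grid.node_coord(node)
        for nb in grid.neighbors8(node):
            if nb <= node:
                continue
            nr, nc = grid.node_coord(nb)
            step = np.hypot(nr - r, nc - c)  # 1 or sqrt(2)
            cost = step * 0.5 * (h[node] + h[nb])
            rows.append(node)
            cols.append(nb)
            data.append(cost)
    m = coo_matrix((data, (rows, cols)), shape=(grid.n_nodes, grid.n_nodes))
    return m.tocsr()


def topographic_path(height: Portrait, source: int, sink: int) -> GeneStateTrajectory:
    """Least-cost path over the elevation landscape of a portrait.

    Elevation is rescaled to a strictly positive floor; each 8-neighbor
    step costs its geometric length (1 or sqrt 2) times the mean rescaled
    elevation of its endpoints. With a stem-minus-tissue difference
    portrait as height, the cheapest route descends along the valleys of
    the landscape. The score is the total path cost.
    """
    grid = height.grid
    for v in (source, sink):
        if not 0 <= v < grid.n_nodes:
            raise ValueError(f"node index {v} outside the grid")
    if source == sink:
        return GeneStateTrajectory(
            path=[source],
            score=0.0,
            per_step_expression=[float(height.values[source])],
            method_tag="topographic",
        )
    costs = _grid_cost_graph(height.values, grid)
    dist, pred = _csgraph_dijkstra(
        costs, directed=False, indices=source, return_predecessors=True
    )
    path = [sink]
    while path[-1] != source:
        p = pred[path[-1]]
        if p < 0:  # pragma: no cover - grid is always connected
            raise ValueError("sink unreachable from source")
        path.append(int(p))
    path.reverse()
    return GeneStateTrajectory(
        path=path,
        score=float(dist[sink]),
        per_step_expression=[float(height.values[v]) for v in path],
        method_tag="topographic",
    )


# ---------------------------------------------------------------------------
# expression along a trajectory
# ---------------------------------------------------------------------------


def trajectory_profile(
    traj: GeneStateTrajectory,
    portraits_along_pt: list[Portrait],
    seg: ModuleSegmentation | None = None,
) -> np.ndarray:
    """Matrix (path position x stage): mean expression of each path element.

    Path elements that are cluster letters require ``seg`` to resolve
    their member nodes; integer elements are taken as grid node indices.
    """
    if not portraits_along_pt:
        raise ValueError("need at least one portrait")
    grid = portraits_along_pt[0].grid
    for p in portraits_along_pt:
        if p.grid != grid:
            raise ValueError("portraits must share one grid")
    member_nodes = []
    for el in traj.path:
        if isinstance(el, (int, np.integer)):
            member_nodes.append(np.array([int(el)]))
        else:
            if seg is None:
                raise ValueError("cluster-letter paths need a segmentation to resolve nodes")
            if seg.grid != grid:
                raise ValueError("segmentation grid differs from portrait grid")
            member_nodes.append(seg.nodes_of_cluster(seg.cluster_of_letter(el)))
    out = np.empty((len(traj.path), len(portraits_along_pt)))
    for i, nodes in enumerate(member_nodes):
        for t, p in enumerate(portraits_along_pt):
            out[i, t] = p.values[nodes].mean()
    return out
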