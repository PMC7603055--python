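"""Decomposing the trained map into expression modules.

Two complementary decompositions are provided. *Spot detection* finds the
connected regions of concerted overexpression that mark cell-type-specific
programs (thresholding group portraits at a high quantile and taking
8-connected components). *Space-filling segmentation* partitions every
grid node into k clusters of similar metagene profiles via k-means, labels
the clusters with capital letters in order of descending expression
variance ("A", "B", ..., "Z", "A1", "B1", ...), classifies each as
spot-variant / low-variant / invariant, and builds the cluster adjacency
graph that gene-state trajectories run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .som import Portrait, SOMGrid, SOMModel, variance_map

VARIANCE_CLASSES = ("spot-variant", "low-variant", "invariant")

_EIGHT_CONN = np.ones((3, 3), dtype=int)  # Moore neighborhood structure


def cluster_letter(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'A1', 31 -> 'F1', 52 -> 'A2', ..."""
    if i < 0:
        raise ValueError("letter index must be nonnegative")
    suffix, base = divmod(i, 26)
    return chr(ord("A") + base) + (str(suffix) if suffix else "")


@dataclass
class SpotModule:
    """A connected overexpression region with its kernel (peak) node."""

    members: frozenset[int]
    kernel: int
    label: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("spot must have at least one member node")
        if self.kernel not in self.members:
            raise ValueError("spot kernel must be a member node")


@dataclass
class ModuleSegmentation:
    """Total node -> cluster labeling plus letters, adjacency, variance classes."""

    grid: SOMGrid
    labels: np.ndarray  # node -> cluster id (0..k-1)
    letters: dict[int, str]
    adjacency: nx.Graph = field(default_factory=nx.Graph)
    variance_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.grid.n_nodes,):
            raise ValueError("labels must assign every grid node a cluster")
        present = set(np.unique(self.labels))
        if not present <= set(self.letters):
            raise ValueError("every non-empty cluster needs a letter")

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def letter_of_node(self, node: int) -> str:
        return self.letters[int(self.labels[node])]

    def nodes_of_cluster(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def cluster_of_letter(self, letter: str) -> int:
        for cid, let in self.letters.items():
            if let == letter:
                return cid
        raise KeyError(f"no cluster labeled {letter!r}")

    def to_frame(self) -> pd.DataFrame:
        coords = self.grid.coords()
        return pd.DataFrame(
            {
                "node_row": coords[:, 0],
                "node_col": coords[:, 1],
                "cluster_letter": [self.letter_of_node(i) for i in range(self.grid.n_nodes)],
                "variance_class": [
                    self.variance_class.get(int(self.labels[i]), "") for i in range(self.grid.n_nodes)
                ],
            }
        )


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------


def detect_spots(
    group_portraits: list[Portrait], quantile: float = 0.98
) -> list[SpotModule]:
    """Overexpression spots from a set of group portraits.

    A node is a spot member if its value strictly exceeds the
    per-portrait ``quantile`` threshold in at least one portrait (an
    all-constant portrait therefore yields no spots). Members are grouped
    into 8-connected components; each component's kernel is the node of
    maximal value in the node-wise maximum over all portraits. Spots are
    labeled "S1", "S2", ... in order of descending kernel height.
    """
    if not group_portraits:
        raise ValueError("need at least one portrait")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    grid = group_portraits[0].grid
    for p in group_portraits[1:]:
        if p.grid != grid:
            raise ValueError("portraits must share one grid")
    member = np.zeros(grid.n_nodes, dtype=bool)
    for p in group_portraits:
        thr = np.quantile(p.values, quantile)
        member |= p.values > thr
    summary = np.max(np.column_stack([p.values for p in group_portraits]), axis=1)
    labeled, n_comp = ndimage.label(
        member.reshape(grid.rows, grid.cols), structure=_EIGHT_CONN
    )
    labeled = labeled.ravel()
    spots = []
    for comp in range(1, n_comp + 1):
        nodes = np.flatnonzero(labeled == comp)
        kernel = nodes[np.argmax(summary[nodes])]
        spots.append((float(summary[kernel]), frozenset(int(n) for n in nodes), int(kernel)))
    spots.sort(key=lambda t: (-t[0], t[2]))
    return [
        SpotModule(members=members, kernel=kernel, label=f"S{i + 1}")
        for i, (_, members, kernel) in enumerate(spots)
    ]


def spots_to_frame(spots: list[SpotModule], grid: SOMGrid) -> pd.DataFrame:
    rows = []
    for s in spots:
        r, c = grid.node_coord(s.kernel)
        rows.append({"label": s.label, "kernel_row": r, "kernel_col": c, "n_nodes": len(s.members)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# space-filling segmentation
# ---------------------------------------------------------------------------


def kmeans_segment(model: SOMModel, k: int = 32, seed: int = 0) -> ModuleSegmentation:
    """Partition all metagenes into k clusters of similar profiles.

    Lloyd's algorithm with k-means++ seeding, best of 10 restarts. Letters
    are assigned in order of descending mean metagene variance, so the
    most variant (tissue-specific) modules receive the early letters and
    the invariant bulk ends up late in the alphabet.
    """
    K = model.grid.n_nodes
    if not 1 <= k <= K:
        raise ValueError(f"k must be in [1, {K}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(model.prototypes)
    raw_labels = _repair_empty_clusters(raw_labels, model.prototypes, k)
    var = variance_map(model)
    # order clusters by descending mean node variance; ties by cluster id
    order = sorted(
        range(k), key=lambda c: (-float(var[raw_labels == c].mean()), c)
    )
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw_labels])
    letters = {i: cluster_letter(i) for i in range(k)}
    seg = ModuleSegmentation(grid=model.grid, labels=labels, letters=letters)
    seg.adjacency = cluster_adjacency(seg, model.grid)
    return seg


def _repair_empty_clusters(labels: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Ensure exactly k non-empty clusters by splitting the largest.

    scikit-learn's k-means relocates empty clusters itself, so this is a
    guard for degenerate data with fewer distinct points than clusters.
    """
    labels = labels.copy()
    present = set(np.unique(labels))
    missing = [c for c in range(k) if c not in present]
    for c in missing:
        sizes = np.bincount(labels, minlength=k)
        big = int(np.argmax(sizes))
        members = np.flatnonzero(labels == big)
        if len(members) < 2:
            raise ValueError(f"cannot form {k} non-empty clusters from the data")
        # move the member farthest from the big cluster's centroid
        centroid = X[members].mean(axis=0)
        far = members[np.argmax(((X[members] - centroid) ** 2).sum(axis=1))]
        labels[far] = c
    return labels


def cluster_adjacency(seg: ModuleSegmentation, grid: SOMGrid) -> nx.Graph:
    """Undirected graph with an edge wherever two clusters touch on the grid."""
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in np.unique(seg.labels))
    labels = seg.labels
    for node in range(grid.n_nodes):
        for nb in grid.neighbors8(node):
            if nb > node and labels[node] != labels[nb]:
                g.add_edge(int(labels[node]), int(labels[nb]))
    return g


def classify_variance(
    seg: ModuleSegmentation, model: SOMModel, spots: list[SpotModule]
) -> ModuleSegmentation:
    """Tag clusters spot-variant / invariant / low-variant.

    A cluster containing a spot kernel is spot-variant. Among the
    remaining clusters the one with minimal mean metagene variance is
    tagged invariant (the bulk of genes that never change); if every
    cluster holds a kernel, the globally least variant one is invariant.
    Everything else is low-variant. Exactly one cluster is invariant.
    """
    var = variance_map(model)
    clusters = [int(c) for c in np.unique(seg.labels)]
    kernel_clusters = {int(seg.labels[s.kernel]) for s in spots}
    classes = {c: ("spot-variant" if c in kernel_clusters else "low-variant") for c in clusters}
    candidates = [c for c in clusters if c not in kernel_clusters] or clusters
    mean_var = {c: float(var[seg.labels == c].mean()) for c in candidates}
    invariant = min(candidates, key=lambda c: (mean_var[c], c))
    classes[invariant] = "invariant"
    seg.variance_class = classes
    return seg
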