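"""Diffusion-based pseudotime ordering of cells.

Cells are embedded by their metagene portraits, connected into a
symmetrized k-nearest-neighbor graph with adaptive Gaussian kernel
weights, and ordered by diffusion distance from a set of root cells
(e.g., the stem compartment). The pseudotime is the Euclidean distance in
the leading diffusion-map coordinates — eigenvectors of the normalized
transition operator scaled by lambda / (1 - lambda) — measured from the
root centroid and affinely rescaled so the root sits at pt = 0 and the
most distant cell at pt = 1. This spectral formulation is a deterministic
stand-in for simulated diffusion random walks: both measure the average
number of diffusion steps needed to reach a cell from the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .som import SOMModel


@dataclass
class CellGraph:
    """Symmetric weighted cell-cell similarity graph."""

    weights: csr_matrix
    cell_ids: list[str]
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class PseudotimeResult:
    """Pseudotime in [0, 1] per cell, with the run's parameters."""

    pt: pd.Series  # index: cell id
    root_cells: list[str]
    knn_k: int
    n_diffusion_components: int

    def __post_init__(self) -> None:
        vals = self.pt.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("pseudotime values must be finite")

    def to_frame(self, lineage: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.pt.index, "pt": self.pt.to_numpy()})
        if lineage is not None:
            df["lineage"] = lineage.reindex(self.pt.index).to_numpy()
        return df


def cell_features_from_model(model: SOMModel) -> pd.DataFrame:
    """Cells x metagene feature matrix (each cell's portrait, flattened)."""
    return pd.DataFrame(model.prototypes.T, index=model.cell_ids)


def knn_graph(cell_features: pd.DataFrame | np.ndarray, k: int = 15) -> CellGraph:
    """Symmetrized kNN graph with adaptive Gaussian kernel weights.

    The bandwidth of cell i is its distance to its ceil(k/2)-th neighbor;
    the weight of edge (i, j) is ``exp(-d_ij^2 / (sigma_i * sigma_j))``.
    Duplicate cells (zero distance, possibly zero bandwidth) receive
    weight 1. An edge exists when either endpoint lists the other among
    its k nearest neighbors.
    """
    if isinstance(cell_features, pd.DataFrame):
        ids = [str(i) for i in cell_features.index]
        X = cell_features.to_numpy(dtype=float)
    else:
        X = np.asarray(cell_features, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)  # column 0 is the cell itself
    dist, idx = dist[:, 1:], idx[:, 1:]
    half = max(int(np.ceil(k / 2)) - 1, 0)
    sigma = dist[:, half].copy()
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    d = dist.ravel()
    denom = sigma[rows] * sigma[cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-(d**2) / denom)
    w[(denom == 0) | ~np.isfinite(w)] = np.where(
        d[(denom == 0) | ~np.isfinite(w)] == 0, 1.0, 0.0
    )
    w[d == 0] = 1.0
    W = csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # symmetrize: union of neighborhoods
    return CellGraph(weights=W, cell_ids=ids, k=k)


def diffusion_pseudotime(
    graph: CellGraph, roots: list[str], n_components: int = 10
) -> PseudotimeResult:
    """Pseudotime as diffusion distance from the root centroid.

    Uses the spectrum of the symmetrically normalized transition operator;
    the top ``n_components`` nontrivial eigenpairs give the diffusion
    coordinates, each scaled by lambda / (1 - lambda). Distances are
    rescaled so min(root pt) = 0 and max(pt) = 1 exactly.
    """
    if not roots:
        raise ValueError("need at least one root cell")
    missing = [r for r in roots if r not in graph.cell_ids]
    if missing:
        raise KeyError(f"root cells not in graph: {missing[:5]}")
    n = graph.n_cells
    W = graph.weights
    if W.nnz and np.all(W.data == 1.0):
        # weight 1 marks zero distance: every connected pair is a duplicate
        raise ValueError("degenerate spectrum: all cells are identical")
    n_comp, comp_labels = connected_components(W, directed=False)
    mask = np.ones(n, dtype=bool)
    if n_comp > 1:
        sizes = np.bincount(comp_labels)
        main = int(np.argmax(sizes))
        warnings.warn(
            f"cell graph has {n_comp} components; using the largest "
            f"({sizes[main]} of {n} cells), remaining cells get pt = 1",
            stacklevel=2,
        )
        mask = comp_labels == main
    idx_map = {c: i for i, c in enumerate(graph.cell_ids)}
    root_idx = [idx_map[r] for r in roots]
    if not any(mask[i] for i in root_idx):
        raise ValueError("no root cell lies in the main graph component")
    sub = W[mask][:, mask].toarray()
    deg = sub.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("isolated cell inside the main component")
    inv_sqrt = 1.0 / np.sqrt(deg)
    A = sub * inv_sqrt[:, None] * inv_sqrt[None, :]
    A = 0.5 * (A + A.T)
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary eigenpair (lambda = 1)
    lam = np.clip(evals[1 : n_components + 1], -1.0, 1.0 - 1e-12)
    if len(lam) == 0 or np.all(np.abs(lam) < 1e-12):
        raise ValueError("degenerate spectrum: all cells are identical")
    vecs = evecs[:, 1 : n_components + 1]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, j]))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    psi = vecs * inv_sqrt[:, None]  # right eigenvectors of the Markov operator
    coords = psi * (lam / (1.0 - lam))[None, :]
    sub_positions = np.flatnonzero(mask)
    pos_in_sub = {int(g): i for i, g in enumerate(sub_positions)}
    sub_roots = [pos_in_sub[i] for i in root_idx if mask[i]]
    centroid = coords[sub_roots].mean(axis=0)
    dist = np.linalg.norm(coords - centroid[None, :], axis=1)
    pt = np.ones(n)
    pt[mask] = dist
    root_min = min(pt[i] for i in root_idx if mask[i])
    span = pt.max() - root_min
    if span <= 0:
        raise ValueError("degenerate spectrum: no spread in diffusion distances")
    pt = (pt - root_min) / span
    pt = np.clip(pt, 0.0, 1.0)
    return PseudotimeResult(
        pt=pd.Series(pt, index=graph.cell_ids),
        root_cells=list(roots),
        knn_k=graph.k,
        n_diffusion_components=n_components,
    )


def pt_spot_profile(
    pt: PseudotimeResult,
    cells_of_lineage: list[str],
    model: SOMModel,
    spot_nodes,
    span: float = 0.5,
) -> dict:
    """Expression of a spot/cluster along pseudotime for one lineage.

    For each lineage cell, the mean portrait value over the spot's nodes
    is paired with the cell's pt. A LOESS curve (tricube-weighted local
    regression, ``span`` = fraction of points per window) summarizes the
    trend; with fewer than 5 cells only the points are returned.

    Returns a dict with ``pt``, ``expression`` (sorted by pt) and
    ``curve`` (an (m, 2) array of (pt, fitted) or None).
    """
    nodes = np.asarray(
        sorted(spot_nodes.members) if hasattr(spot_nodes, "members") else list(spot_nodes),
        dtype=int,
    )
    if nodes.size == 0:
        raise ValueError("spot has no nodes")
    missing = [c for c in cells_of_lineage if c not in model._cell_index]
    if missing:
        raise KeyError(f"unknown cells: {missing[:5]}")
    cols = [model._cell_index[c] for c in cells_of_lineage]
    expr = model.prototypes[np.ix_(nodes, cols)].mean(axis=0)
    t = pt.pt.loc[list(cells_of_lineage)].to_numpy()
    order = np.argsort(t, kind="stable")
    t, expr = t[order], expr[order]
    curve = None
    if len(t) >= 5:
        fitted = lowess(expr, t, frac=span, return_sorted=True)
        curve = np.asarray(fitted)
    return {"pt": t, "expression": expr, "curve": curve}
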