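"""Batch self-organizing map on gene expression profiles.

Genes are the training samples; the components of each sample are the
cells' centered log expression values. The trained map places one
*metagene* (prototype vector) at every node of a rectangular grid so that
genes with similar expression profiles map to nearby nodes. Reading the
prototype values of a single cell across all nodes yields that cell's
expression *portrait* — a 2-D image of its transcriptome.

Training is deterministic batch SOM: every epoch assigns each gene to its
best-matching unit (BMU, nearest prototype in Euclidean distance) and then
replaces each prototype by the neighborhood-weighted mean of the assigned
gene profiles. The Gaussian neighborhood radius shrinks linearly over the
epochs, so late epochs approach plain k-means refinement of an ordered
map. Prototypes are initialized on the plane spanned by the first two
principal components of the gene profiles, which makes the map orientation
reproducible without any randomness in the common case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .matrix import ExpressionMatrix
from .preprocess import loglog_transform

SCALE_TAGS = ("logfc", "loglogfc")


@dataclass(frozen=True)
class SOMGrid:
    """Rectangular grid geometry; nodes are (row, col), row-major linearized."""

    rows: int = 60
    cols: int = 60

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows * self.cols < 4:
            raise ValueError("grid needs rows, cols >= 1 and at least 4 nodes")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"node ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def node_coord(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_nodes:
            raise ValueError(f"node index {index} out of range")
        return divmod(index, self.cols)

    def coords(self) -> np.ndarray:
        """(K, 2) array of (row, col) for all nodes in row-major order."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def neighbors8(self, index: int) -> list[int]:
        """Moore (8-connected) neighbors of a node."""
        r, c = self.node_coord(index)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if 0 <= nr < self.rows and 0 <= nc < self.cols:
                    out.append(nr * self.cols + nc)
        return out


@dataclass
class Portrait:
    """One value per grid node: the transcriptome image of a cell or group."""

    grid: SOMGrid
    values: np.ndarray
    subject: str
    scale_tag: str = "logfc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_nodes:
            raise ValueError(
                f"portrait has {self.values.size} values for a "
                f"{self.grid.rows}x{self.grid.cols} grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("portrait values must be finite")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}")

    def as_image(self) -> np.ndarray:
        return self.values.reshape(self.grid.rows, self.grid.cols)


@dataclass
class SOMModel:
    """Trained map: prototypes (K x n_cells), gene->BMU map, and metadata."""

    grid: SOMGrid
    prototypes: np.ndarray
    bmu: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.bmu = np.asarray(self.bmu, dtype=int)
        K = self.grid.n_nodes
        if self.prototypes.shape != (K, len(self.cell_ids)):
            raise ValueError("prototypes must be (n_nodes, n_cells)")
        if self.bmu.shape != (len(self.gene_ids),):
            raise ValueError("bmu must hold one node index per gene")
        if not np.all(np.isfinite(self.prototypes)):
            raise ValueError("prototypes must be finite")
        if self.bmu.size and (self.bmu.min() < 0 or self.bmu.max() >= K):
            raise ValueError("bmu indices out of grid range")
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def genes_of_node(self, node: int) -> list[str]:
        return [g for g, b in zip(self.gene_ids, self.bmu) if b == node]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _pca_plane_init(
    grid: SOMGrid, data: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Prototypes spanning the first two principal components of the genes.

    Falls back to seeded sampling of data rows when the profile cloud is
    degenerate (fewer than two directions of variance).
    """
    K = grid.n_nodes
    mean = data.mean(axis=0)
    centered = data - mean
    # economical SVD; data is genes x cells
    try:
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological input
        svals = np.zeros(1)
        vt = np.zeros((1, data.shape[1]))
    n = max(data.shape[0], 2)
    sds = svals / np.sqrt(n - 1)
    if len(sds) < 2 or sds[1] <= 1e-12 * max(sds[0], 1.0):
        # degenerate cloud: seed prototypes from the data rows themselves
        idx = rng.integers(0, data.shape[0], size=K)
        return data[idx].copy()
    # grid coordinates scaled to [-1, 1] along each axis
    coords = grid.coords().astype(float)
    ax_r = coords[:, 0] / max(grid.rows - 1, 1) * 2.0 - 1.0
    ax_c = coords[:, 1] / max(grid.cols - 1, 1) * 2.0 - 1.0
    protos = (
        mean[None, :]
        + np.outer(ax_r, sds[0] * vt[0])
        + np.outer(ax_c, sds[1] * vt[1])
    )
    return protos


def _bmu_of(data: np.ndarray, prototypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching unit per row of ``data``; ties -> lowest node index.

    Returns (bmu indices, Euclidean distance to the BMU).
    """
    # squared distances via the expansion ||x||^2 - 2 x.p + ||p||^2
    x2 = np.einsum("ij,ij->i", data, data)[:, None]
    p2 = np.einsum("ij,ij->i", prototypes, prototypes)[None, :]
    d2 = x2 - 2.0 * data @ prototypes.T + p2
    np.maximum(d2, 0.0, out=d2)
    bmu = np.argmin(d2, axis=1)  # argmin takes the first minimum: lowest index
    dist = np.sqrt(d2[np.arange(len(bmu)), bmu])
    return bmu, dist


def _gaussian_1d(n: int, sigma: float) -> np.ndarray:
    d = np.arange(n)[:, None] - np.arange(n)[None, :]
    return np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))


def _smooth_grid(field_: np.ndarray, grid: SOMGrid, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing of a (K, d) node field over the grid."""
    hr = _gaussian_1d(grid.rows, sigma)
    hc = _gaussian_1d(grid.cols, sigma)
    cube = field_.reshape(grid.rows, grid.cols, -1)
    cube = np.tensordot(hr, cube, axes=(1, 0))
    cube = np.tensordot(hc, cube, axes=(1, 1)).transpose(1, 0, 2)
    return cube.reshape(grid.n_nodes, -1)


def train_som(
    data: ExpressionMatrix,
    grid: SOMGrid | None = None,
    epochs: int = 20,
    seed: int = 0,
    radius_start: float | None = None,
    radius_final: float = 0.5,
) -> SOMModel:
    """Train a batch SOM on gene logFC profiles.

    Deterministic given ``seed`` (randomness is only used for the
    degenerate-data initialization fallback). The Gaussian neighborhood
    radius decays linearly from ``radius_start`` (default
    ``max(rows, cols) / 2``) to ``radius_final`` across the epochs.
    """
    if grid is None:
        grid = SOMGrid()
    if data.layer_tag != "logfc":
        raise ValueError(
            f"SOM training expects a logfc layer, got {data.layer_tag!r}; "
            "run compute_logfc first"
        )
    if data.n_genes < 2 or data.n_cells < 2:
        raise ValueError("need at least 2 genes and 2 cells to train")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if grid.n_nodes > 4 * data.n_genes:
        warnings.warn(
            f"grid has {grid.n_nodes} nodes for only {data.n_genes} genes; "
            "the map will be sparse",
            stacklevel=2,
        )
    X = data.values
    rng = np.random.default_rng(seed)
    prototypes = _pca_plane_init(grid, X, rng)
    if radius_start is None:
        radius_start = max(grid.rows, grid.cols) / 2.0
    radii = np.linspace(radius_start, radius_final, epochs)
    qe_history: list[float] = []
    bmu = np.zeros(data.n_genes, dtype=int)
    for sigma in radii:
        bmu, _ = _bmu_of(X, prototypes)
        counts = np.bincount(bmu, minlength=grid.n_nodes).astype(float)
        sums = np.zeros((grid.n_nodes, data.n_cells))
        np.add.at(sums, bmu, X)
        num = _smooth_grid(sums, grid, sigma)
        den = _smooth_grid(counts[:, None], grid, sigma)[:, 0]
        nonzero = den > 1e-300
        prototypes = np.where(nonzero[:, None], num / np.maximum(den, 1e-300)[:, None], prototypes)
        bmu, dist = _bmu_of(X, prototypes)
        qe_history.append(float(dist.mean()))
    return SOMModel(
        grid=grid,
        prototypes=prototypes,
        bmu=bmu,
        gene_ids=list(data.gene_ids),
        cell_ids=list(data.cell_ids),
        training_meta={
            "epochs": epochs,
            "seed": seed,
            "radius_start": float(radius_start),
            "radius_final": float(radius_final),
            "quantization_error": qe_history[-1],
            "qe_history": qe_history,
        },
    )


# ---------------------------------------------------------------------------
# queries on a trained model
# ---------------------------------------------------------------------------


def assign_bmu(model: SOMModel, profile: np.ndarray) -> int:
    """Node whose prototype is nearest (Euclidean); ties -> lowest index."""
    profile = np.asarray(profile, dtype=float).ravel()
    if profile.size != model.n_cells:
        raise ValueError(
            f"profile has {profile.size} components, model has {model.n_cells} cells"
        )
    bmu, _ = _bmu_of(profile[None, :], model.prototypes)
    return int(bmu[0])


def portrait_of_cell(model: SOMModel, cell: str, scale: str = "logfc") -> Portrait:
    """One cell's transcriptome image: the cell's column of the prototypes."""
    if scale not in SCALE_TAGS:
        raise ValueError(f"scale must be one of {SCALE_TAGS}")
    try:
        j = model._cell_index[cell]
    except KeyError:
        raise KeyError(f"unknown cell id {cell!r}") from None
    vals = model.prototypes[:, j].copy()
    if scale == "loglogfc":
        vals = loglog_transform(vals)
    return Portrait(grid=model.grid, values=vals, subject=cell, scale_tag=scale)


def mean_portrait(
    model: SOMModel, cells: list[str], scale: str = "logfc", subject: str | None = None
) -> Portrait:
    """Node-wise mean of the member cells' logFC portraits.

    The loglog rescale, when requested, is applied to the mean (not
    averaged over rescaled portraits).
    """
    if len(cells) == 0:
        raise ValueError("mean_portrait needs a nonempty cell set")
    if scale not in SCALE_TAGS:
        raise ValueError(f"scale must be one of {SCALE_TAGS}")
    idx = [model._cell_index[c] if c in model._cell_index else None for c in cells]
    missing = [c for c, i in zip(cells, idx) if i is None]
    if missing:
        raise KeyError(f"unknown cell ids: {missing[:5]}")
    vals = model.prototypes[:, idx].mean(axis=1)
    if scale == "loglogfc":
        vals = loglog_transform(vals)
    return Portrait(
        grid=model.grid,
        values=vals,
        subject=subject or f"mean({len(cells)} cells)",
        scale_tag=scale,
    )


def population_map(model: SOMModel) -> np.ndarray:
    """Genes per node (how many genes have each node as their BMU)."""
    return np.bincount(model.bmu, minlength=model.grid.n_nodes)


def variance_map(model: SOMModel, groups: dict[str, list[str]] | None = None) -> np.ndarray:
    """Per-node variance of metagene expression across cells.

    With ``groups`` given (label -> cell ids, at least two groups), the
    variance is taken across the group-mean portraits instead — this is the
    between-cell-type variability of each metagene.
    """
    if groups is None:
        if model.n_cells < 2:
            raise ValueError("variance undefined for a single cell")
        return model.prototypes.var(axis=1)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a grouped variance map")
    means = np.column_stack(
        [mean_portrait(model, cells, scale="logfc").values for cells in groups.values()]
    )
    return means.var(axis=1)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: SOMModel, path) -> None:
    """Write the model to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("prototypes", data=model.prototypes)
        f.create_dataset("bmu", data=model.bmu)
        f.create_dataset("grid", data=np.array([model.grid.rows, model.grid.cols]))
        st = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("gene_ids", data=np.array(model.gene_ids, dtype=object), dtype=st)
        f.create_dataset("cell_ids", data=np.array(model.cell_ids, dtype=object), dtype=st)
        meta = f.create_group("meta")
        for k, v in model.training_meta.items():
            meta.attrs[k] = v


def load_model(path) -> SOMModel:
    with h5py.File(path, "r") as f:
        rows, cols = (int(v) for v in f["grid"][...])
        return SOMModel(
            grid=SOMGrid(rows, cols),
            prototypes=f["prototypes"][...],
            bmu=f["bmu"][...],
            gene_ids=[g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][...]],
            cell_ids=[c.decode() if isinstance(c, bytes) else str(c) for c in f["cell_ids"][...]],
            training_meta={k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in f["meta"].attrs.items()},
        )
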