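"""RNA-velocity estimation and its projection onto the SOM grid.

Under first-order splicing kinetics the unspliced abundance u of a gene
relaxes toward gamma * s, where s is the spliced abundance and gamma the
degradation/splicing rate ratio. The residual ``v = u - gamma * s`` is the
RNA velocity: positive when transcription outruns degradation (rising
expression), negative when it lags. gamma is fitted per gene as the
through-origin slope of u against s on cells at the expression extremes,
where the steady-state assumption is most plausible.

On the map, each metagene's velocity vector is the mean of its member
genes' velocity rows (one component per cell). The high-dimensional
vector is turned into a 2-D grid arrow by correlating it with the
prototype differences toward each of the node's 8 neighbors and summing
the positively correlated directions — the same neighbor-difference
projection principle used to draw velocity fields on cell embeddings,
applied here in gene-state space. Arrows point toward local attractors of
maximum transcription; integrating the interpolated field yields velocity
trajectories and a watershed partition into attractor basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .som import Portrait, SOMGrid, SOMModel
from .trajectory import GeneStateTrajectory


@dataclass
class GeneKinetics:
    """Per-gene steady-state slope and velocity matrix."""

    gene_ids: list[str]
    cell_ids: list[str]
    gamma: np.ndarray  # NaN where unfittable
    velocity: np.ndarray  # genes x cells; NaN rows for unfittable genes
    fit_quantile: float

    @property
    def fitted(self) -> np.ndarray:
        """Boolean mask of genes with a valid gamma."""
        return np.isfinite(self.gamma)


@dataclass
class VelocityField:
    """Per-node velocity vectors, 2-D arrows, attractors and basins."""

    grid: SOMGrid
    node_velocity: np.ndarray  # K x n_cells, zero rows where no fitted member
    arrows: np.ndarray  # K x 2, (d_row, d_col), |arrow| <= 1
    has_members: np.ndarray  # K bools
    attractors: list[int] = field(default_factory=list)
    basin: dict[int, int] = field(default_factory=dict)  # node -> attractor
    watershed: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        coords = self.grid.coords()
        speed = np.linalg.norm(self.arrows, axis=1)
        return pd.DataFrame(
            {
                "row": coords[:, 0],
                "col": coords[:, 1],
                "arrow_dx": self.arrows[:, 1],
                "arrow_dy": self.arrows[:, 0],
                "speed": speed,
                "basin": [self.basin.get(i, -1) for i in range(self.grid.n_nodes)],
                "is_attractor": [i in set(self.attractors) for i in range(self.grid.n_nodes)],
            }
        )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def fit_gamma(
    s: ExpressionMatrix, u: ExpressionMatrix, quantile: float = 0.05
) -> GeneKinetics:
    """Steady-state ratio fit: per-gene slope of u on s through the origin.

    Only cells in the bottom and top ``quantile`` of the gene's spliced
    abundance enter the fit (expression extremes approximate steady
    state). Genes whose selected spliced values are all zero are flagged
    unfittable (gamma = NaN) and excluded downstream.
    """
    if s.layer_tag != "spliced" or u.layer_tag != "unspliced":
        raise ValueError("expected layers tagged 'spliced' and 'unspliced'")
    if s.gene_ids != u.gene_ids or s.cell_ids != u.cell_ids:
        raise ValueError("spliced and unspliced matrices must share genes and cells")
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must lie in (0, 0.5]")
    S, U = s.values, u.values
    lo = np.quantile(S, quantile, axis=1, keepdims=True)
    hi = np.quantile(S, 1.0 - quantile, axis=1, keepdims=True)
    extreme = (S <= lo) | (S >= hi)
    sel_s = np.where(extreme, S, 0.0)
    sel_u = np.where(extreme, U, 0.0)
    ss = np.einsum("ij,ij->i", sel_s, sel_s)
    us = np.einsum("ij,ij->i", sel_u, sel_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = us / ss
    gamma[ss == 0] = np.nan
    gamma = np.where(np.isfinite(gamma), np.maximum(gamma, 0.0), np.nan)
    velocity = U - gamma[:, None] * S
    velocity[~np.isfinite(gamma)] = np.nan
    return GeneKinetics(
        gene_ids=list(s.gene_ids),
        cell_ids=list(s.cell_ids),
        gamma=gamma,
        velocity=velocity,
        fit_quantile=quantile,
    )


# ---------------------------------------------------------------------------
# aggregation to metagenes and grid arrows
# ---------------------------------------------------------------------------


def metagene_velocity(model: SOMModel, kin: GeneKinetics) -> tuple[np.ndarray, np.ndarray]:
    """Per-node velocity vector: mean over fitted member genes' rows.

    Returns ``(node_velocity, has_members)``; nodes without any fitted
    member gene get a zero vector and ``has_members=False``.
    """
    unknown = [g for g in kin.gene_ids if g not in model._gene_index]
    if unknown:
        raise ValueError(f"kinetics genes absent from the model: {unknown[:5]}")
    if kin.cell_ids != model.cell_ids:
        raise ValueError("kinetics and model must share cell ids")
    K = model.grid.n_nodes
    node_velocity = np.zeros((K, model.n_cells))
    counts = np.zeros(K)
    for g_idx, gene in enumerate(kin.gene_ids):
        if not np.isfinite(kin.gamma[g_idx]):
            continue
        node = model.bmu[model._gene_index[gene]]
        node_velocity[node] += kin.velocity[g_idx]
        counts[node] += 1
    has = counts > 0
    node_velocity[has] /= counts[has, None]
    return node_velocity, has


def grid_vector_field(
    model: SOMModel,
    node_velocity: np.ndarray,
    has_members: np.ndarray | None = None,
    min_speed: float = 1e-9,
) -> VelocityField:
    """Project node velocity vectors onto 2-D grid arrows.

    For node m and each 8-neighbor n, the Pearson correlation between the
    node's velocity vector and the prototype difference ``p_n - p_m``
    measures how much the velocity points "toward" n in expression space.
    The arrow is the positive-correlation-weighted sum of the unit grid
    directions, scaled by the total positive weight so that its length is
    at most one grid unit and shrinks when positively correlated
    directions disagree. Nodes with zero velocity (or no positive
    correlation, or an undefined correlation) get a zero arrow.
    ``min_speed`` is the numerical floor below which a node's velocity
    vector counts as zero (guards against round-off residue of an exact
    steady state).
    """
    grid = model.grid
    K = grid.n_nodes
    node_velocity = np.asarray(node_velocity, dtype=float)
    if node_velocity.shape != (K, model.n_cells):
        raise ValueError("node_velocity must be (n_nodes, n_cells)")
    if has_members is None:
        has_members = np.linalg.norm(node_velocity, axis=1) > 0
    arrows = np.zeros((K, 2))
    coords = grid.coords().astype(float)
    for m in range(K):
        v = node_velocity[m]
        v_c = v - v.mean()
        v_norm = np.linalg.norm(v_c)
        if np.linalg.norm(v) <= min_speed or v_norm <= min_speed:
            continue
        acc = np.zeros(2)
        total_w = 0.0
        for n in grid.neighbors8(m):
            delta = model.prototypes[n] - model.prototypes[m]
            d_c = delta - delta.mean()
            d_norm = np.linalg.norm(d_c)
            if d_norm == 0:  # constant difference: correlation undefined
                continue
            w = float(v_c @ d_c / (v_norm * d_norm))
            if w <= 0:
                continue
            direction = coords[n] - coords[m]
            acc += w * direction / np.linalg.norm(direction)
            total_w += w
        if total_w > 0:
            arrows[m] = acc / total_w
    return VelocityField(
        grid=grid, node_velocity=node_velocity, arrows=arrows, has_members=np.asarray(has_members, bool)
    )


# ---------------------------------------------------------------------------
# attractors, streamlines, basins
# ---------------------------------------------------------------------------


def detect_attractors(
    field: VelocityField, summary_expression: Portrait, tol: float = 1e-3
) -> list[int]:
    """Nodes where the flow vanishes at a local expression maximum.

    A node is an attractor if its arrow length is below ``tol`` and its
    summary expression strictly exceeds that of all its 8 neighbors
    (strictness keeps flat background regions from flooding the list).
    """
    if summary_expression.grid != field.grid:
        raise ValueError("portrait grid differs from field grid")
    vals = summary_expression.values
    speed = np.linalg.norm(field.arrows, axis=1)
    out = []
    for m in range(field.grid.n_nodes):
        if speed[m] >= tol:
            continue
        if all(vals[m] > vals[n] for n in field.grid.neighbors8(m)):
            out.append(m)
    field.attractors = out
    return out


def _bilinear_arrow(field: VelocityField, pos: np.ndarray) -> np.ndarray:
    """Bilinearly interpolated arrow at a fractional (row, col) position."""
    grid = field.grid
    r = np.clip(pos[0], 0.0, grid.rows - 1.0)
    c = np.clip(pos[1], 0.0, grid.cols - 1.0)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, grid.rows - 1), min(c0 + 1, grid.cols - 1)
    fr, fc = r - r0, c - c0
    a = field.arrows.reshape(grid.rows, grid.cols, 2)
    return (
        a[r0, c0] * (1 - fr) * (1 - fc)
        + a[r1, c0] * fr * (1 - fc)
        + a[r0, c1] * (1 - fr) * fc
        + a[r1, c1] * fr * fc
    )


def velocity_trajectories(
    field: VelocityField,
    starts: list[int],
    step: float = 0.5,
    max_steps: int = 500,
    tol: float = 1e-3,
) -> tuple[list[GeneStateTrajectory], dict[int, int]]:
    """Integrate streamlines of the arrow field and label basins.

    Forward Euler on the bilinearly interpolated field from each start
    node; integration stops when the local arrow is shorter than ``tol``,
    after ``max_steps``, or on leaving the grid. Each start is assigned to
    the basin of the attractor nearest its endpoint; starts whose
    8-neighborhood contains nodes draining to a different attractor are
    marked as watershed nodes. Requires ``detect_attractors`` to have run
    (the field's attractor list may be empty, in which case basins are
    empty too).
    """
    grid = field.grid
    coords = grid.coords().astype(float)
    att_coords = coords[field.attractors] if field.attractors else None
    trajs = []
    endpoint_attractor: dict[int, int] = {}
    for start in starts:
        pos = coords[start].copy()
        path_nodes = [int(start)]
        for _ in range(max_steps):
            arrow = _bilinear_arrow(field, pos)
            if np.linalg.norm(arrow) < tol:
                break
            pos = pos + step * arrow
            if not (0 <= pos[0] <= grid.rows - 1 and 0 <= pos[1] <= grid.cols - 1):
                pos = np.clip(pos, [0, 0], [grid.rows - 1, grid.cols - 1])
                node = grid.node_index(int(round(pos[0])), int(round(pos[1])))
                if node != path_nodes[-1]:
                    path_nodes.append(node)
                break
            node = grid.node_index(int(round(pos[0])), int(round(pos[1])))
            if node != path_nodes[-1] and node not in path_nodes:
                path_nodes.append(node)
        if att_coords is not None:
            d = np.linalg.norm(att_coords - pos[None, :], axis=1)
            endpoint_attractor[start] = int(field.attractors[int(np.argmin(d))])
        trajs.append(
            GeneStateTrajectory(
                path=path_nodes,
                score=float(len(path_nodes) - 1),
                per_step_expression=[],
                method_tag="velocity",
            )
        )
    # watershed: starts whose neighbors drain to a different attractor
    watershed: set[int] = set()
    start_set = set(starts)
    for start in starts:
        mine = endpoint_attractor.get(start)
        if mine is None:
            continue
        for nb in grid.neighbors8(start):
            other = endpoint_attractor.get(nb)
            if nb in start_set and other is not None and other != mine:
                watershed.add(start)
                break
    basin = {s: a for s, a in endpoint_attractor.items() if s not in watershed}
    field.basin = basin
    field.watershed = watershed
    return trajs, basin


def transition_projection(
    field: VelocityField,
    source_node: int,
    sink_node: int,
    corridor: float = 2.0,
    margin: float = 2.0,
) -> float:
    """Mean arrow projection onto the source-to-sink axis in the transition.

    The transition region is the corridor of nodes within ``corridor``
    grid units of the straight segment between the two spot kernels,
    excluding ``margin`` units around each endpoint. A positive value
    means the flow in the region points from the source spot toward the
    sink spot.
    """
    coords = field.grid.coords().astype(float)
    p0, p1 = coords[source_node], coords[sink_node]
    seg = p1 - p0
    length = np.linalg.norm(seg)
    if length == 0:
        raise ValueError("source and sink nodes coincide")
    axis = seg / length
    proj = []
    for node in range(field.grid.n_nodes):
        rel = coords[node] - p0
        along = float(rel @ axis)
        if along < margin or along > length - margin:
            continue
        if np.linalg.norm(rel - along * axis) > corridor:
            continue
        proj.append(float(field.arrows[node] @ axis))
    if not proj:
        raise ValueError("transition corridor contains no nodes; kernels too close")
    return float(np.mean(proj))
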