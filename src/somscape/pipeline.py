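"""End-to-end orchestration: counts in, landscape + trajectories out.

The stages mirror the analysis workflow: center the counts into logFC,
train the SOM, summarize cell types into mean portraits, detect
overexpression spots and segment the map into lettered modules, extract a
gene-state trajectory per lineage (widest path on the capacity network
plus a topographic least-cost path on the stem-minus-tissue difference
landscape), order cells by diffusion pseudotime from the root cell type,
and — when spliced/unspliced layers are available — build the
RNA-velocity vector field with its attractors and basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .matrix import ExpressionMatrix
from .preprocess import compute_logfc, filter_genes
from .pseudotime import (
    PseudotimeResult,
    cell_features_from_model,
    diffusion_pseudotime,
    knn_graph,
)
from .segmentation import (
    ModuleSegmentation,
    SpotModule,
    classify_variance,
    detect_spots,
    kmeans_segment,
)
from .som import Portrait, SOMGrid, SOMModel, mean_portrait, train_som
from .trajectory import (
    GeneStateTrajectory,
    build_capacity_graph,
    max_capacity_path,
    topographic_path,
)
from .velocity import (
    VelocityField,
    detect_attractors,
    fit_gamma,
    grid_vector_field,
    metagene_velocity,
    velocity_trajectories,
)


@dataclass
class LineageTrajectories:
    """Per-lineage endpoints and the two path constructions."""

    lineage: str
    source_letter: str
    sink_letter: str
    source_node: int
    sink_node: int
    capacity_path: GeneStateTrajectory
    topo_path: GeneStateTrajectory


@dataclass
class PipelineResult:
    config: RunConfig
    model: SOMModel
    group_portraits: dict[str, Portrait]
    spots: list[SpotModule]
    segmentation: ModuleSegmentation
    trajectories: dict[str, LineageTrajectories] = field(default_factory=dict)
    pseudotime: PseudotimeResult | None = None
    velocity_field: VelocityField | None = None


def cells_of(annotations: pd.DataFrame, **criteria) -> list[str]:
    """Cell ids matching all given column == value criteria."""
    mask = pd.Series(True, index=annotations.index)
    for col, val in criteria.items():
        mask &= annotations[col] == val
    return annotations.loc[mask, "cell_id"].tolist()


def group_mean_portraits(
    model: SOMModel, annotations: pd.DataFrame, by: str = "cell_type", scale: str = "logfc"
) -> dict[str, Portrait]:
    out = {}
    for group, sub in annotations.groupby(by, sort=True):
        cells = [c for c in sub["cell_id"] if c in model._cell_index]
        if cells:
            out[str(group)] = mean_portrait(model, cells, scale=scale, subject=str(group))
    return out


def find_lineage_endpoints(
    model: SOMModel,
    seg: ModuleSegmentation,
    spots: list[SpotModule],
    annotations: pd.DataFrame,
    lineage: str,
    root_cell_type: str = "stem",
) -> tuple[SpotModule, SpotModule]:
    """Source (stem) and sink (tissue) spots for one lineage.

    The source is the spot whose kernel is highest in the root cells'
    mean portrait; the sink the spot whose kernel is highest in the mean
    portrait of the lineage's terminal cells (cell_type == lineage label,
    falling back to all non-root cells of the lineage).
    """
    if not spots:
        raise ValueError("no spots detected; cannot locate endpoints")
    root_cells = cells_of(annotations, cell_type=root_cell_type)
    if not root_cells:
        raise ValueError(f"no cells of root type {root_cell_type!r}")
    terminal = cells_of(annotations, lineage=lineage, cell_type=lineage)
    if not terminal:
        lin = annotations[annotations["lineage"] == lineage]
        terminal = lin.loc[lin["cell_type"] != root_cell_type, "cell_id"].tolist()
    if not terminal:
        raise ValueError(f"no terminal cells for lineage {lineage!r}")
    stem_portrait = mean_portrait(model, root_cells, subject=f"root:{root_cell_type}")
    tissue_portrait = mean_portrait(model, terminal, subject=f"tissue:{lineage}")
    source = max(spots, key=lambda s: stem_portrait.values[s.kernel])
    sink = max(spots, key=lambda s: tissue_portrait.values[s.kernel])
    return source, sink


def lineage_trajectories(
    model: SOMModel,
    seg: ModuleSegmentation,
    spots: list[SpotModule],
    annotations: pd.DataFrame,
    lineage: str,
    root_cell_type: str = "stem",
) -> LineageTrajectories:
    """Both trajectory constructions for one lineage."""
    source_spot, sink_spot = find_lineage_endpoints(
        model, seg, spots, annotations, lineage, root_cell_type
    )
    lin_cells = cells_of(annotations, lineage=lineage)
    root_cells = cells_of(annotations, cell_type=root_cell_type)
    lineage_cells = sorted(set(lin_cells) | set(root_cells))
    lin_portrait = mean_portrait(
        model, lineage_cells, scale="loglogfc", subject=f"lineage:{lineage}"
    )
    g = build_capacity_graph(seg, lin_portrait)
    source_letter = seg.letter_of_node(source_spot.kernel)
    sink_letter = seg.letter_of_node(sink_spot.kernel)
    cap_traj = max_capacity_path(g, source_letter, sink_letter)
    terminal = cells_of(annotations, lineage=lineage, cell_type=lineage) or lin_cells
    stem_p = mean_portrait(model, root_cells, subject="stem-mean")
    tissue_p = mean_portrait(model, terminal, subject=f"{lineage}-mean")
    height = Portrait(
        grid=model.grid,
        values=stem_p.values - tissue_p.values,
        subject=f"difference:{root_cell_type}-{lineage}",
    )
    topo = topographic_path(height, source_spot.kernel, sink_spot.kernel)
    return LineageTrajectories(
        lineage=lineage,
        source_letter=source_letter,
        sink_letter=sink_letter,
        source_node=source_spot.kernel,
        sink_node=sink_spot.kernel,
        capacity_path=cap_traj,
        topo_path=topo,
    )


def run_pipeline(
    counts: ExpressionMatrix,
    annotations: pd.DataFrame,
    spliced: ExpressionMatrix | None = None,
    unspliced: ExpressionMatrix | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage on one dataset; velocity only with both layers."""
    cfg = config or RunConfig()
    if cfg.min_cells > 0:
        counts = filter_genes(counts, cfg.min_cells)
    logfc = compute_logfc(counts, pseudocount=cfg.pseudocount)
    grid = SOMGrid(cfg.grid_rows, cfg.grid_cols)
    model = train_som(logfc, grid, epochs=cfg.epochs, seed=cfg.seed)

    portraits = group_mean_portraits(model, annotations)
    spots = detect_spots(list(portraits.values()), quantile=cfg.spot_quantile)
    seg = kmeans_segment(model, k=min(cfg.k_segments, grid.n_nodes), seed=cfg.seed)
    seg = classify_variance(seg, model, spots)

    result = PipelineResult(
        config=cfg,
        model=model,
        group_portraits=portraits,
        spots=spots,
        segmentation=seg,
    )

    lineages = sorted(set(annotations.get("lineage", pd.Series(dtype=str)).dropna()))
    for lin in lineages:
        try:
            result.trajectories[lin] = lineage_trajectories(
                model, seg, spots, annotations, lin, cfg.root_cell_type
            )
        except ValueError:
            continue  # lineage without usable endpoints

    roots = cells_of(annotations, cell_type=cfg.root_cell_type)
    if roots:
        graph = knn_graph(cell_features_from_model(model), k=min(cfg.pt_k, model.n_cells - 1))
        result.pseudotime = diffusion_pseudotime(graph, roots, n_components=cfg.pt_components)

    if spliced is not None and unspliced is not None:
        kin = fit_gamma(spliced, unspliced, quantile=cfg.velocity_quantile)
        node_vel, has = metagene_velocity(model, kin)
        fieldv = grid_vector_field(model, node_vel, has)
        summary = Portrait(
            grid=model.grid,
            values=np.max(np.column_stack([p.values for p in portraits.values()]), axis=1),
            subject="summary-max",
        )
        detect_attractors(fieldv, summary)
        starts = [i for i in range(grid.n_nodes)]
        velocity_trajectories(fieldv, starts)
        result.velocity_field = fieldv
    return result
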