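"""Reading and writing the on-disk formats of the pipeline.

Matrices travel either as MatrixMarket triplets (genes x cells, 1-based
indices per the MTX standard) with ``genes.tsv`` / ``barcodes.tsv``
sidecars, or as dense TSV with gene ids in the first column and cell ids
in the header. Annotations are CSV with ``cell_id``, ``cell_type`` and
optional ``lineage``. All writers round-trip through the readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix


def write_mtx(mat: ExpressionMatrix, directory, prefix: str = "") -> None:
    """MTX triplet plus gene/barcode TSV sidecars."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(d / f"{prefix}matrix.mtx"), sparse.coo_matrix(mat.values))
    pd.Series(mat.gene_ids).to_csv(d / f"{prefix}genes.tsv", sep="\t", index=False, header=False)
    pd.Series(mat.cell_ids).to_csv(d / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx(directory, prefix: str = "", layer_tag: str = "raw") -> ExpressionMatrix:
    d = Path(directory)
    mtx = d / f"{prefix}matrix.mtx"
    genes = d / f"{prefix}genes.tsv"
    barcodes = d / f"{prefix}barcodes.tsv"
    for p in (mtx, genes, barcodes):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
    values = spio.mmread(str(mtx)).toarray().astype(float)
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    return ExpressionMatrix(values, gene_ids, cell_ids, layer_tag)


def write_dense_tsv(mat: ExpressionMatrix, path) -> None:
    """Dense TSV: header row = cell ids, first column = gene ids."""
    mat.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_dense_tsv(path, layer_tag: str = "raw") -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(df, layer_tag)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    required = {"cell_id", "cell_type"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    annotations.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str)
    if "cell_id" not in df.columns or "cell_type" not in df.columns:
        raise ValueError(f"{path} lacks cell_id / cell_type columns")
    return df


def portrait_png(portrait, path, dpi_scale: int = 1) -> None:
    """Blue-to-red diverging image of a portrait, symmetric about zero.

    One pixel per node (``dpi_scale`` enlarges by integer replication).
    """
    from matplotlib import colormaps
    from matplotlib.image import imsave

    img = portrait.as_image()
    vmax = max(float(np.abs(img).max()), 1e-12)
    norm = (img / vmax + 1.0) / 2.0  # [-vmax, vmax] -> [0, 1]
    if dpi_scale > 1:
        norm = np.kron(norm, np.ones((dpi_scale, dpi_scale)))
    imsave(path, colormaps["RdBu_r"](norm))
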