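"""Expression matrix container used throughout the pipeline.

The convention is genes in rows, cells in columns — genes are the training
samples of the SOM, cells are the vector components. A ``layer_tag`` records
which representation the values are in (raw counts, centered log fold
changes, the signed-log compression thereof, or spliced/unspliced
abundances) so downstream operations can check they receive what they
expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LAYERS = ("raw", "logfc", "loglogfc", "spliced", "unspliced")

# raw-like layers must be nonnegative; logfc rows must be centered
_NONNEGATIVE_LAYERS = ("raw", "spliced", "unspliced")


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    layer_tag
        One of ``raw``, ``logfc``, ``loglogfc``, ``spliced``, ``unspliced``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "raw"
    _gene_index: dict[str, int] = field(init=False, repr=False)
    _cell_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids are not unique")
        if self.layer_tag not in VALID_LAYERS:
            raise ValueError(
                f"unknown layer_tag {self.layer_tag!r}; expected one of {VALID_LAYERS}"
            )
        self._check_layer()
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    def _check_layer(self) -> None:
        bad = ~np.isfinite(self.values)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        if self.layer_tag in _NONNEGATIVE_LAYERS:
            neg = self.values < 0
            if neg.any():
                g, c = np.argwhere(neg)[0]
                raise ValueError(
                    f"negative {self.layer_tag} value at gene "
                    f"{self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
                )
        if self.layer_tag == "logfc":
            row_means = self.values.mean(axis=1)
            worst = int(np.argmax(np.abs(row_means)))
            if abs(row_means[worst]) > 1e-9:
                raise ValueError(
                    f"logfc row for gene {self.gene_ids[worst]!r} has mean "
                    f"{row_means[worst]:.3g}, expected 0"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self._cell_index[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_tag: str = "raw") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(i) for i in df.index],
            cell_ids=[str(c) for c in df.columns],
            layer_tag=layer_tag,
        )
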