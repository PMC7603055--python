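"""Centering raw expression into logFC and the signed-log (loglogFC) rescale.

The SOM consumes gene-wise centered log expression: for every gene the log
count in a cell minus that gene's mean log count over all cells, so a value
of zero means "at this gene's typical level". The signed-log compression of
logFC is used for trajectory edge weights and for "coast-line" portraits
that separate over- from under-expression at fold change 1.
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix


def compute_logfc(raw: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Gene-wise centered log2 expression.

    ``out[g, c] = log2(raw[g, c] + pseudocount) - mean_c log2(raw[g, .] + pseudocount)``

    Every output row is mean-zero by construction. ``pseudocount`` must be
    positive so that zero counts stay finite (default 1).
    """
    if raw.layer_tag != "raw":
        raise ValueError(f"expected a raw layer, got {raw.layer_tag!r}")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    log_vals = np.log2(raw.values + pseudocount)
    centered = log_vals - log_vals.mean(axis=1, keepdims=True)
    # re-center once more: guards against accumulation in very long rows
    centered -= centered.mean(axis=1, keepdims=True)
    return ExpressionMatrix(centered, raw.gene_ids, raw.cell_ids, layer_tag="logfc")


def loglog_transform(x):
    """Signed log compression of logFC: ``sign(x) * log2(1 + |x|)``.

    Odd, strictly increasing, and zero exactly at logFC = 0 — the
    "coast-line" between over- and under-expression. Compresses large
    amplitudes while leaving the sign structure of the landscape intact.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("loglog_transform requires finite input")
    out = np.sign(x) * np.log2(1.0 + np.abs(x))
    return out if out.ndim else float(out)


def filter_genes(raw: ExpressionMatrix, min_cells: int = 0) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in at least ``min_cells`` cells.

    Gene order is preserved. ``min_cells=0`` is the identity; an empty
    result raises rather than returning a zero-row matrix.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    if min_cells > raw.n_cells:
        raise ValueError(
            f"min_cells={min_cells} exceeds the number of cells ({raw.n_cells})"
        )
    detected = (raw.values > 0).sum(axis=1)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError(f"no genes pass filter (min_cells={min_cells})")
    return ExpressionMatrix(
        raw.values[keep],
        [g for g, k in zip(raw.gene_ids, keep) if k],
        raw.cell_ids,
        layer_tag=raw.layer_tag,
    )
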