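"""Functional annotation of expression modules.

Three views: hypergeometric overrepresentation of a gene set among a
module's member genes, a gene set enrichment Z-score (GSZ) profile of the
set's mean expression across cell groups, and the gene set map locating
each set gene's BMU on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .som import SOMModel


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: name <tab> description <tab> gene ids."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def overrepresentation(
    module_genes: set[str], gene_set: GeneSet, universe: set[str]
) -> dict:
    """Hypergeometric upper-tail test of set overrepresentation in a module.

    Population = universe, successes = set genes in the universe, draws =
    module size; p = P(overlap >= observed). Returns overlap, p and
    log10(p).
    """
    if not universe:
        raise ValueError("universe is empty")
    module_genes = set(module_genes) & set(universe)
    if not module_genes:
        raise ValueError("module has no genes in the universe")
    in_universe = set(gene_set.genes) & set(universe)
    overlap = len(module_genes & in_universe)
    M, n, N = len(universe), len(in_universe), len(module_genes)
    if n == 0:
        p = 1.0
    else:
        p = float(hypergeom.sf(overlap - 1, M, n, N))
        p = min(max(p, 0.0), 1.0)
    return {
        "overlap": overlap,
        "set_size": n,
        "module_size": N,
        "p": p,
        "log10p": float(np.log10(p)) if p > 0 else -np.inf,
    }


def module_enrichment_table(
    module_gene_lists: dict[str, set[str]],
    gene_sets: list[GeneSet],
    universe: set[str],
) -> pd.DataFrame:
    """Overrepresentation of every set in every module, BH-corrected per module."""
    rows = []
    for module, genes in module_gene_lists.items():
        res = []
        for s in gene_sets:
            r = overrepresentation(genes, s, universe)
            r.update(module=module, set=s.name)
            res.append(r)
        pvals = [r["p"] for r in res]
        fdr = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        for r, q in zip(res, fdr):
            r["fdr"] = float(q)
        rows.extend(res)
    cols = ["module", "set", "overlap", "set_size", "module_size", "p", "fdr", "log10p"]
    return pd.DataFrame(rows, columns=cols)


def gsz_profile(
    data: ExpressionMatrix,
    gene_set: GeneSet,
    groups: dict[str, list[str]],
    model: SOMModel | None = None,
) -> pd.Series:
    """Gene set enrichment Z-score per cell group.

    For group g, with per-gene mean logFC over the group's cells:
    ``Z = (mean over set genes - mean over all genes) / (sd over all genes / sqrt(n_set))``.
    A one-sample Z of the set mean against the global background; zero
    when the set is the whole universe. With a model given, only set
    genes actually mapped on the SOM count. Undefined (zero background
    sd) groups are returned as NaN.
    """
    if data.layer_tag != "logfc":
        raise ValueError("gsz_profile expects logfc data")
    mapped = set(gene_set.genes) & set(data.gene_ids)
    if model is not None:
        mapped &= set(model.gene_ids)
    if not mapped:
        raise ValueError(f"no gene of set {gene_set.name!r} is mapped")
    set_idx = [data.gene_index(g) for g in sorted(mapped)]
    n_set = len(set_idx)
    out = {}
    for gname, cells in groups.items():
        cols = [data.cell_index(c) for c in cells]
        per_gene = data.values[:, cols].mean(axis=1)
        sd_all = per_gene.std(ddof=0)
        if sd_all == 0:
            out[gname] = np.nan
            continue
        z = (per_gene[set_idx].mean() - per_gene.mean()) / (sd_all / np.sqrt(n_set))
        out[gname] = float(z)
    return pd.Series(out, name=gene_set.name)


def gene_set_map(model: SOMModel, gene_set: GeneSet) -> tuple[pd.DataFrame, list[str]]:
    """BMU coordinates of each mapped set gene plus the unmapped remainder."""
    rows, unmapped = [], []
    for g in sorted(gene_set.genes):
        if g in model._gene_index:
            r, c = model.grid.node_coord(int(model.bmu[model._gene_index[g]]))
            rows.append({"gene": g, "row": r, "col": c})
        else:
            unmapped.append(g)
    return pd.DataFrame(rows, columns=["gene", "row", "col"]), unmapped
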