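"""One-versus-rest cell-type enrichment of mediator genes.

Given a cell x gene count matrix with cell-type labels, each requested gene
gets, per type, a log2 fold change of depth-normalized mean expression in
the type versus all other cells, and the fraction of cells (from raw
counts) expressing it.  A gene absent from the matrix is reported as
not-detected rather than raising, mirroring how secreted proteins without
brain transcripts are handled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["one_vs_rest_enrichment", "assign_enriched_type"]

PSEUDOCOUNT = 1e-9
DEPTH_TARGET = 1e4


def one_vs_rest_enrichment(
    counts: pd.DataFrame,
    labels: pd.Series,
    genes: list[str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per (gene, cell type): log2FC of counts-per-10k means and the
    fraction of cells in the type with a nonzero raw count."""
    labels = labels.reindex(counts.index)
    if labels.isna().any():
        raise ValueError("every cell needs a label")
    type_counts = labels.value_counts()
    small = type_counts[type_counts < 2]
    if len(small):
        raise ValueError(f"cell types with fewer than 2 cells: {small.index.tolist()}")
    if genes is None:
        genes = list(counts.columns)

    X = counts.to_numpy(dtype=float)
    depth = X.sum(axis=1)
    if np.any(depth == 0):
        raise ValueError("cells with zero total counts")
    norm = X / depth[:, None] * DEPTH_TARGET

    rows = []
    gene_index = {g: i for i, g in enumerate(counts.columns)}
    for gene in genes:
        if gene not in gene_index:
            for ct in type_counts.index:
                rows.append({"gene": gene, "cell_type": ct, "log2fc": np.nan,
                             "pct_expressing": np.nan, "n_cells": int(type_counts[ct]),
                             "detected": False})
            continue
        j = gene_index[gene]
        for ct in type_counts.index:
            in_type = (labels == ct).to_numpy()
            mu_t = norm[in_type, j].mean()
            mu_r = norm[~in_type, j].mean()
            log2fc = float(np.log2((mu_t + pseudocount) / (mu_r + pseudocount)))
            pct = float((X[in_type, j] > 0).mean())
            rows.append({"gene": gene, "cell_type": ct, "log2fc": log2fc,
                         "pct_expressing": pct, "n_cells": int(in_type.sum()),
                         "detected": bool(X[:, j].sum() > 0)})
    return pd.DataFrame(rows)


def assign_enriched_type(
    profile: pd.DataFrame, min_pct: float = 0.1
) -> dict[str, str]:
    """Map each detected gene to the cell type with maximal log2FC among
    types where at least ``min_pct`` of cells express it."""
    out: dict[str, str] = {}
    for gene, sub in profile.groupby("gene"):
        ok = sub[(sub["pct_expressing"] >= min_pct) & sub["detected"]]
        if len(ok):
            out[str(gene)] = str(ok.loc[ok["log2fc"].idxmax(), "cell_type"])
    return out
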