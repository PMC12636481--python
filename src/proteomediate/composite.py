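"""PCA composite scores over named analyte subsets.

PC1 of the z-scored member columns (eigendecomposition of the correlation
matrix) summarises a correlated panel — the Neurodegeneration Score over
the 4-marker synaptic panel, the Mediator PC1 over validated mediators, or
cell-type-filtered mediator subsets.  The PC sign is arbitrary, so scores
are oriented to correlate nonnegatively with a designated anchor column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CompositeScore", "composite_score", "celltype_subset_score"]


@dataclass
class CompositeScore:
    member_ids: list[str]
    loadings: pd.Series
    variance_explained: float
    scores: pd.Series
    anchor_id: str
    flipped: bool

    def summary(self) -> str:
        lines = [
            f"PC1 composite over {len(self.member_ids)} members "
            f"(anchor {self.anchor_id!r}{', sign flipped' if self.flipped else ''})",
            f"variance explained: {self.variance_explained:.3f}",
            "loadings:",
        ]
        lines += [f"  {k:<20}{v: .4f}" for k, v in self.loadings.items()]
        return "\n".join(lines)


def composite_score(values: pd.DataFrame, anchor_id: str | None = None) -> CompositeScore:
    """PC1 loadings, variance share, and oriented per-sample scores.

    ``values`` must be complete (impute first) with >=2 member columns and
    >=3 samples.  The anchor defaults to the member with the largest
    absolute PC1 loading.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 member columns")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if values.isna().any().any():
        raise ValueError("composite requires complete data; impute first")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = values.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance members: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / len(Z)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    loadings = evecs[:, 0]
    var_explained = float(evals[0] / evals.sum())
    scores = Z @ loadings

    if anchor_id is None:
        anchor_id = values.columns[int(np.argmax(np.abs(loadings)))]
    if anchor_id not in values.columns:
        raise KeyError(f"anchor {anchor_id!r} not among members")
    anchor = Z[:, values.columns.get_loc(anchor_id)]
    flipped = bool(np.dot(scores, anchor) < 0)
    if flipped:
        loadings, scores = -loadings, -scores
    return CompositeScore(
        member_ids=list(values.columns),
        loadings=pd.Series(loadings, index=values.columns, name="loading"),
        variance_explained=var_explained,
        scores=pd.Series(scores, index=values.index, name="pc1"),
        anchor_id=str(anchor_id),
        flipped=flipped,
    )


def celltype_subset_score(
    mediators: list[str],
    celltype_map: dict[str, str],
    requested_types: set[str] | list[str],
    values: pd.DataFrame,
    anchor_id: str | None = None,
) -> CompositeScore:
    """Composite over the mediators whose enriched cell type is requested
    (e.g. a vascular composite over endothelial/pericyte/SMC-enriched
    mediators)."""
    requested = set(requested_types)
    missing = [m for m in mediators if m not in celltype_map]
    if missing:
        raise KeyError(f"mediators missing from cell-type map: {missing}")
    available = set(celltype_map.values())
    unknown = requested - available
    if unknown:
        raise KeyError(f"requested cell types absent from map: {sorted(unknown)}")
    members = [m for m in mediators if celltype_map[m] in requested]
    if not members:
        raise ValueError("no mediators map to the requested cell types")
    return composite_score(values[members], anchor_id)
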