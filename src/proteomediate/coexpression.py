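"""Lean signed weighted co-expression analysis.

The network is the signed weighted graph a_ij = ((1 + cor_ij)/2)^beta, with
the soft-threshold beta chosen by the scale-free topology criterion over a
scanned power range.  Topological overlap (TOM) smooths the adjacency by
shared neighborhoods; modules are cut from average-linkage clustering of
1 - TOM by a height scan that maximizes the number of clusters meeting the
minimum size.  Module eigengenes (PC1 of the member submatrix), kME
(analyte-eigengene correlations), and a cross-cohort preservation statistic
(correlation of the members' pairwise-correlation structure between
cohorts) complete the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ModuleAssignment",
    "scale_free_fit",
    "soft_threshold_scan",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene_kme",
    "module_preservation",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    labels: pd.Series                      # analyte -> module label
    power: int | None
    scan: pd.DataFrame | None              # per-power signed R^2, mean connectivity
    eigengenes: pd.DataFrame | None = None
    kme: pd.DataFrame | None = None

    def module_members(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency fit.

    Connectivities are grouped into ``n_bins`` equal-width bins (exact
    value groups when there are few distinct values); log10 frequency is
    regressed on log10 mean connectivity, and the R^2 is signed by the
    negated slope so that only decreasing (power-law-like) distributions
    score positively.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("constant connectivity: scale-free fit undefined")
    if k.min() <= 0:
        k = k + 1e-12
    uniq = np.unique(k)
    if len(uniq) <= n_bins:
        centers = uniq
        counts = np.array([(k == u).sum() for u in uniq], dtype=float)
    else:
        # equal-width bins over the connectivity range: frequencies must be
        # free to vary for a frequency-vs-connectivity fit to mean anything
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        edges[-1] += 1e-12
        which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
        centers, counts = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            centers.append(k[sel].mean())
            counts.append(sel.sum())
        centers, counts = np.array(centers), np.array(counts, dtype=float)
    if len(centers) < 3:
        raise ValueError("too few distinct connectivity values for a fit")
    lx, ly = np.log10(centers), np.log10(counts)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2)


def signed_adjacency(corr: np.ndarray | pd.DataFrame, power: int) -> np.ndarray:
    """a_ij = ((1 + cor_ij)/2)^power with zero diagonal."""
    c = np.asarray(corr, dtype=float)
    if np.any(np.abs(c) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.clip(c, -1, 1)) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def soft_threshold_scan(
    values: pd.DataFrame,
    powers: range | list[int] = range(15, 27),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Evaluate candidate soft-threshold powers on scale-free topology.

    Returns the per-power table (signed R^2, mean connectivity) and the
    chosen power: the smallest one reaching ``r2_threshold``, else the
    argmax of signed R^2.
    """
    if values.shape[1] < 20:
        raise ValueError("need at least 20 analytes for a soft-threshold scan")
    corr = np.corrcoef(values.to_numpy(dtype=float), rowvar=False)
    rows = []
    for p in powers:
        a = signed_adjacency(corr, p)
        k = a.sum(axis=1)
        rows.append({"power": p, "signed_r2": scale_free_fit(k, n_bins),
                     "mean_connectivity": float(k.mean())})
    scan = pd.DataFrame(rows).set_index("power")
    hits = scan.index[scan["signed_r2"] >= r2_threshold]
    chosen = int(hits[0]) if len(hits) else int(scan["signed_r2"].idxmax())
    return scan, chosen


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), diagonal 1."""
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray, analyte_ids: list[str] | None = None, min_size: int = 5
) -> pd.Series:
    """Cut average-linkage clusters of 1 - TOM into modules of >= min_size.

    Cut heights are scanned from the dendrogram's merge heights; the cut
    maximizing the number of cohesive clusters of size >= min_size wins
    (ties go to the cut assigning more analytes, then to the finer cut).
    A cluster counts as cohesive only when its mean within-cluster overlap
    clearly exceeds the matrix-wide background — this keeps a near-root cut
    from sweeping unrelated analytes into one giant "module".  The trivial
    everything-in-one-cluster partition is not considered structure.
    Analytes in smaller or non-cohesive clusters are labelled "unassigned".
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if analyte_ids is None:
        analyte_ids = [f"A{i}" for i in range(n)]
    if n < min_size:
        raise ValueError(f"fewer analytes ({n}) than min_size ({min_size})")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    off = tom[np.triu_indices(n, k=1)]
    background = float(off.mean())
    cohesion_floor = background + 0.25 * (float(off.max()) - background)

    def cohesive_members(members: np.ndarray) -> np.ndarray:
        # keep members whose median overlap with the rest of the cluster
        # clears the floor: stray background analytes swept in by the cut
        # are trimmed instead of inflating (or masking) a module
        sub = tom[np.ix_(members, members)]
        med = np.nanmedian(np.where(np.eye(len(members), dtype=bool), np.nan, sub), axis=1)
        return members[med > cohesion_floor]

    heights = np.unique(Z[:, 2])
    best = None
    eps = 1e-12
    for h in heights:
        labels = fcluster(Z, t=h - eps, criterion="distance")
        sizes = np.bincount(labels)
        if (labels == labels[0]).all():
            continue
        modules = []
        for c in np.where(sizes >= min_size)[0]:
            keep = cohesive_members(np.where(labels == c)[0])
            if len(keep) >= min_size:
                modules.append(keep)
        n_assigned = int(sum(len(m) for m in modules))
        key = (len(modules), n_assigned, -h)
        if best is None or key > best[0]:
            best = (key, modules)
    out = pd.Series(UNASSIGNED, index=pd.Index(analyte_ids, name="analyte_id"), dtype=object)
    if best is None or best[0][0] == 0:
        return out
    _, modules = best
    # name modules by decreasing size for stable labels
    for rank, members in enumerate(
        sorted(modules, key=lambda m: (-len(m), int(m[0]))), start=1
    ):
        out.iloc[members] = f"module{rank}"
    return out


def module_eigengene_kme(
    values: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes (oriented PC1 scores) and the kME table.

    The eigengene is PC1 of the z-scored member submatrix, oriented to
    correlate positively with the mean member profile; kME is every
    analyte's correlation with every eigengene.
    """
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no labeled modules")
    eigengenes = {}
    for mod in sorted(modules):
        members = labels.index[labels == mod]
        X = values[list(members)].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [m for m, s in zip(members, sd) if s == 0]
            raise ValueError(f"zero-variance members in {mod}: {bad}")
        Z = (X - X.mean(axis=0)) / sd
        _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
        scores = Z @ vt[0]
        if np.dot(scores, Z.mean(axis=1)) < 0:
            scores = -scores
        eigengenes[mod] = scores
    eg = pd.DataFrame(eigengenes, index=values.index)
    V = values.to_numpy(dtype=float)
    Vz = (V - V.mean(axis=0)) / np.where(V.std(axis=0, ddof=0) == 0, 1.0, V.std(axis=0, ddof=0))
    Ez = (eg - eg.mean()) / eg.std(ddof=0)
    kme = pd.DataFrame(
        Vz.T @ Ez.to_numpy() / len(values), index=values.columns, columns=eg.columns
    )
    return eg, kme


def correlation_preservation(corr_a: np.ndarray, corr_b: np.ndarray) -> float:
    """Pearson r between the upper triangles of two correlation matrices."""
    ca, cb = np.asarray(corr_a, dtype=float), np.asarray(corr_b, dtype=float)
    if ca.shape != cb.shape or ca.shape[0] < 3:
        raise ValueError("need matching correlation matrices over >= 3 members")
    iu = np.triu_indices(ca.shape[0], k=1)
    return float(stats.pearsonr(ca[iu], cb[iu])[0])


def module_preservation(
    members: list[str], values_a: pd.DataFrame, values_b: pd.DataFrame
) -> float:
    """Correlation of the module's pairwise co-expression structure between
    two cohorts: Pearson r of the vectorized upper triangles of the member
    correlation matrices.  1 means the co-expression pattern is maintained;
    ~0 means it is not."""
    if len(members) < 3:
        raise ValueError("need at least 3 members for a preservation score")
    missing = [m for m in members if m not in values_a.columns or m not in values_b.columns]
    if missing:
        raise KeyError(f"members absent from a cohort: {missing}")
    ca = np.corrcoef(values_a[list(members)].to_numpy(dtype=float), rowvar=False)
    cb = np.corrcoef(values_b[list(members)].to_numpy(dtype=float), rowvar=False)
    return correlation_preservation(ca, cb)
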