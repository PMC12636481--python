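"""Cross-platform concordance, surrogate selection, and the abundance-matched
bootstrap sensitivity analysis.

When a marker measured on one platform (e.g. an immunoassay pTau) has no
concordant counterpart on the other, a surrogate is chosen from a
user-supplied candidate pool by correlation strength.  Surrogate specificity
is then checked against a null of random analytes matched to the surrogate's
abundance profile (joint decile bins on mean and variance of the transformed
values): if matched random proteins recapitulate the observed correlation,
the surrogate is not specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .io import ProteinMatrix

__all__ = [
    "SurrogateMap",
    "platform_concordance",
    "select_surrogate",
    "surrogate_sensitivity",
]


@dataclass
class SurrogateMap:
    target: str
    surrogate: str
    r: float
    q: float | None
    empirical_p: float | None
    n_matched_pool: int | None
    candidate_pool: list[str]


def _paired(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    return joined.iloc[:, 0].to_numpy(dtype=float), joined.iloc[:, 1].to_numpy(dtype=float)


def platform_concordance(
    matrix_a: ProteinMatrix,
    matrix_b: ProteinMatrix,
    pairs: list[tuple[str, str]],
    r_min: float = 0.3,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-pair correlation across matched samples, with BH q over pairs.

    Both matrices must be on their transformed (log) scale.  A pair is
    flagged concordant when q < 0.05 and r >= r_min.
    """
    if matrix_a.transform == "raw" or matrix_b.transform == "raw":
        raise ValueError("transform both matrices before concordance testing")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for aid, bid in pairs:
        va, vb = _paired(matrix_a.values[aid], matrix_b.values[bid])
        if len(va) < 10:
            raise ValueError(f"fewer than 10 matched samples for pair ({aid}, {bid})")
        r, p = corr(va, vb)
        rows.append({"analyte_a": aid, "analyte_b": bid, "r": float(r), "p": float(p),
                     "n": len(va)})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["concordant"] = (table["q"] < 0.05) & (table["r"] >= r_min)
    return table


def select_surrogate(
    target: str,
    candidate_ids: list[str],
    matrix_b: ProteinMatrix,
    target_values: pd.Series,
) -> SurrogateMap:
    """Pick the candidate maximizing |r| with the target values; ties break
    lexicographically by analyte id."""
    if not candidate_ids:
        raise ValueError("candidate list is empty")
    best: tuple[float, str] | None = None
    best_r = np.nan
    for cid in sorted(candidate_ids):
        va, vb = _paired(target_values, matrix_b.values[cid])
        if len(va) < 3 or np.std(va) == 0 or np.std(vb) == 0:
            continue
        r, _ = stats.pearsonr(va, vb)
        if best is None or abs(r) > best[0] + 1e-15:
            best = (abs(float(r)), cid)
            best_r = float(r)
    if best is None:
        raise ValueError("all candidate correlations undefined")
    return SurrogateMap(
        target=target, surrogate=best[1], r=best_r, q=None,
        empirical_p=None, n_matched_pool=None, candidate_pool=sorted(candidate_ids),
    )


def _decile_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def surrogate_sensitivity(
    target_values: pd.Series,
    surrogate: str,
    matrix_b: ProteinMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
    min_pool: int = 20,
) -> tuple[float, pd.Series]:
    """Empirical p of the surrogate's |r| against abundance-matched nulls.

    The null pool holds analytes sharing the surrogate's joint (mean,
    variance) decile bin, computed from platform-B internal statistics only;
    bins widen (with a warning) until the pool reaches ``min_pool``.
    Empirical p uses the add-one convention and so is never 0.
    """
    if surrogate not in matrix_b.values.columns:
        raise KeyError(f"surrogate {surrogate!r} not in matrix")
    V = matrix_b.values.to_numpy(dtype=float)
    cols = list(matrix_b.values.columns)
    j_sur = cols.index(surrogate)
    means, variances = np.nanmean(V, axis=0), np.nanvar(V, axis=0)

    bins = n_bins
    while True:
        mb = _decile_bins(means, bins)
        vb = _decile_bins(variances, bins)
        pool = np.where((mb == mb[j_sur]) & (vb == vb[j_sur]))[0]
        pool = pool[pool != j_sur]
        if len(pool) >= min_pool or bins == 1:
            break
        bins -= 1
        warnings.warn(f"matched pool below {min_pool}; widening bins to {bins}")
    if len(pool) < min_pool:
        warnings.warn(f"matched pool has only {len(pool)} analytes even at 1 bin")

    tv, sv = _paired(target_values, matrix_b.values[surrogate])
    observed = abs(stats.pearsonr(tv, sv)[0])

    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=n_boot, replace=True)
    null = np.empty(n_boot)
    for i, j in enumerate(draws):
        ta, nb = _paired(target_values, matrix_b.values.iloc[:, j])
        null[i] = abs(stats.pearsonr(ta, nb)[0]) if np.std(nb) > 0 else 0.0
    p = (1.0 + float((null >= observed).sum())) / (n_boot + 1.0)
    summary = pd.Series(
        {"observed_abs_r": observed, "null_mean": null.mean(),
         "null_q95": float(np.quantile(null, 0.95)), "pool_size": len(pool)}
    )
    return p, summary
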