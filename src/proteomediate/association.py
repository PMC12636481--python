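"""Covariate-adjusted linear associations with standardized betas and BH-FDR.

The convention throughout: the outcome and the predictor of interest are
z-scored, adjustment covariates (age, sex, ...) enter untransformed, and the
reported ``beta_std`` is the predictor's coefficient — the standard-deviation
change in outcome per standard-deviation change in predictor, comparable
across analytes.  Q-values are Benjamini-Hochberg step-up, corrected within
one scan (one outcome, one subgroup, all analytes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinMatrix, CovariateTable

__all__ = ["AssociationResult", "adjusted_regression", "bh_fdr", "proteome_scan"]


@dataclass
class AssociationResult:
    analyte_id: str
    beta_std: float
    se: float
    t: float
    p: float
    n: int
    q: float | None = None


def zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance variable")
    return (v - v.mean()) / sd


def adjusted_regression(
    y, x, covariates: pd.DataFrame | np.ndarray | None = None, analyte_id: str = "x"
) -> AssociationResult:
    """OLS of z-scored y on z-scored x plus raw covariates."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must be aligned")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("y and x must be finite")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    n = len(y)
    n_pred = 1 + (0 if cov is None else cov.shape[1])
    if n < n_pred + 2:
        raise ValueError(f"too few samples (n={n}) for {n_pred} predictors")
    design = [zscore(x)[:, None]] if cov is None else [zscore(x)[:, None], cov]
    X = sm.add_constant(np.hstack(design))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(zscore(y), X).fit()
    return AssociationResult(
        analyte_id=analyte_id,
        beta_std=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        n=n,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _scan_ols(X: np.ndarray, Y: np.ndarray, coef_idx: int):
    """OLS of each column of Y on a shared design X; stats for one coefficient.

    Returns (beta, se, t, p) arrays over columns of Y.
    """
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid * resid).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[coef_idx, coef_idx])
    b = beta[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return b, se, t, p


def proteome_scan(
    matrix: ProteinMatrix,
    outcome,
    covariates: CovariateTable | pd.DataFrame | None = None,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    subgroup: pd.Series | None = None,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Adjusted association of every analyte with one outcome.

    ``subgroup`` is a boolean per-sample filter (e.g. amyloid-negative);
    listwise deletion drops samples with a missing outcome.  Returns a
    table with beta_std/se/t/p/q/n per analyte, q corrected over the scan.
    """
    outcome = pd.Series(np.asarray(outcome, dtype=float), index=matrix.values.index)
    keep = outcome.notna()
    if subgroup is not None:
        keep &= subgroup.reindex(matrix.values.index).fillna(False).astype(bool)
    if keep.sum() == 0:
        raise ValueError("empty subgroup")
    analytes = [a for a in matrix.analyte_ids if a not in set(exclude)]
    V = matrix.values.loc[keep, analytes].to_numpy(dtype=float)
    y = zscore(outcome[keep].to_numpy())
    n = int(keep.sum())

    cov_arr = np.empty((n, 0))
    if covariates is not None:
        frame = covariates.data if isinstance(covariates, CovariateTable) else covariates
        cov_arr = frame.loc[keep[keep].index, list(covariate_names)].to_numpy(dtype=float)

    sd = V.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [analytes[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance analytes: {bad}")
    Vz = (V - V.mean(axis=0)) / sd

    # each analyte is the z-scored predictor; regress y on [1, cov, analyte]
    base = np.column_stack([np.ones(n), cov_arr])
    k = base.shape[1] + 1
    betas = np.empty(len(analytes))
    ses = np.empty(len(analytes))
    # bordered normal equations: shared base block, one varying column
    G00 = base.T @ base
    G00_inv = np.linalg.inv(G00)
    b0y = base.T @ y
    for j in range(len(analytes)):
        v = Vz[:, j]
        u = base.T @ v
        s = float(v @ v)
        schur = s - float(u @ G00_inv @ u)
        if schur <= 1e-12 * s:
            raise ValueError(f"analyte {analytes[j]!r} collinear with covariates")
        bj = (float(v @ y) - float(u @ G00_inv @ b0y)) / schur
        g0 = G00_inv @ (b0y - u * bj)
        resid = y - base @ g0 - v * bj
        sigma2 = float(resid @ resid) / (n - k)
        betas[j] = bj
        ses[j] = np.sqrt(sigma2 / schur)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(ses > 0, betas / ses, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)
    return pd.DataFrame(
        {
            "analyte_id": analytes,
            "beta_std": betas,
            "se": ses,
            "t": tvals,
            "p": pvals,
            "q": bh_fdr(pvals),
            "n": n,
        }
    ).set_index("analyte_id")
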