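"""Little's test for data missing completely at random.

The statistic compares, across missingness patterns, the observed-variable
means of each pattern with the grand means estimated by EM under a single
multivariate normal model:

    d2 = sum_j n_j (ybar_obs,j - mu_obs,j)' Sigma_obs,j^{-1} (ybar_obs,j - mu_obs,j)

with df = sum_j p_j - p and a chi-square reference distribution.  Under
MCAR the pattern means agree with the grand means up to sampling noise;
systematic (value-dependent) missingness inflates d2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LittleResult", "little_mcar_test", "em_mean_cov"]


@dataclass
class LittleResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int


def em_mean_cov(
    X: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """ML mean and covariance of a multivariate normal with missing values.

    Standard EM: the E-step fills each row's missing block with its
    conditional expectation given the observed block and accumulates the
    conditional covariance into the second-moment matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("rows with no observed values cannot be used")
    mu = np.nanmean(X, axis=0)
    Xf = np.where(miss, mu, X)
    sigma = np.cov(Xf, rowvar=False, bias=True) + 1e-6 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        patterns[key.tobytes()] = np.where((miss == key).all(axis=1))[0]

    for _ in range(max_iter):
        exx = np.zeros((p, p))
        ex = np.zeros(p)
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            Xr = X[rows]
            if not m.any():
                ex += Xr.sum(axis=0)
                exx += Xr.T @ Xr
                continue
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(m, o)]
            reg = np.linalg.solve(soo, smo.T).T
            cond_cov = sigma[np.ix_(m, m)] - reg @ smo.T
            filled = Xr.copy()
            filled[:, m] = mu[m] + (Xr[:, o] - mu[o]) @ reg.T
            ex += filled.sum(axis=0)
            second = filled.T @ filled
            second[np.ix_(m, m)] += len(rows) * cond_cov
            exx += second
        mu_new = ex / n
        sigma_new = exx / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def little_mcar_test(table: pd.DataFrame, ridge: float | None = None) -> LittleResult:
    """Little's chi-square MCAR test on a table with missing cells."""
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if not miss.any():
        raise ValueError("no missing data")
    if miss.all(axis=1).any():
        raise ValueError("a missingness pattern has no observed variables")

    mu, sigma = em_mean_cov(X)

    d2 = 0.0
    df = 0
    n_patterns = 0
    for key in np.unique(miss, axis=0):
        rows = np.where((miss == key).all(axis=1))[0]
        if len(rows) == 0:
            raise ValueError("a missingness pattern has no rows after filtering")
        o = ~key
        n_patterns += 1
        ybar = X[np.ix_(rows, np.where(o)[0])].mean(axis=0)
        soo = sigma[np.ix_(o, o)]
        cond = np.linalg.cond(soo)
        if not np.isfinite(cond) or cond > 1e12:
            eps = ridge if ridge is not None else 1e-6 * np.trace(soo) / soo.shape[0]
            warnings.warn(f"singular pattern covariance; applying ridge {eps:.3g}")
            soo = soo + eps * np.eye(soo.shape[0])
        diff = ybar - mu[o]
        d2 += len(rows) * float(diff @ np.linalg.solve(soo, diff))
        df += int(o.sum())
    df -= p
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else 1.0
    return LittleResult(statistic=float(d2), df=df, p_value=p_value, n_patterns=n_patterns)
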