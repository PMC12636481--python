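"""Baron-Kenny mediation with BCa bootstrap inference and E-values.

For one (exposure, mediator, outcome) triple the three OLS path models are

    mediator ~ exposure + covariates          -> a
    outcome  ~ mediator + exposure + cov.     -> b, c' (direct effect)
    outcome  ~ exposure + covariates          -> c  (total effect)

with the indirect effect quantified by the product of coefficients a*b and
the exact same-sample OLS identity c = c' + a*b.  Inference on a*b uses
nonparametric case resampling with bias-corrected and accelerated (BCa)
confidence intervals; E-values quantify the unmeasured confounding needed
to explain the observed indirect effect away.

The proteome-wide screen applies this machinery to every non-exposure
analyte against each outcome marker, with joint-significance gating
(BH-FDR on the a- and b-path p-values separately within a screen) followed
by a BCa interval excluding zero and bootstrap sign consistency; candidates
must pass every outcome with a consistent indirect-effect sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .association import bh_fdr, zscore
from .io import ProteinMatrix, CovariateTable

__all__ = [
    "PathEstimates",
    "MediationModel",
    "MediationResults",
    "ScreenResult",
    "mediation_paths",
    "bootstrap_indirect",
    "bca_interval",
    "e_value",
    "mediation_screen",
    "validate_mediators",
    "replicate_screen",
]

_COND_LIMIT = 1e10


@dataclass
class PathEstimates:
    a: float
    b: float
    c_prime: float
    c_total: float
    se_a: float
    se_b: float
    se_c_prime: float
    se_c_total: float
    n: int

    @property
    def indirect(self) -> float:
        return self.a * self.b


def _design(cov: np.ndarray | None, *cols: np.ndarray) -> np.ndarray:
    n = len(cols[0])
    parts = [np.ones((n, 1))]
    if cov is not None and cov.size:
        parts.append(cov)
    parts.extend(c[:, None] for c in cols)
    return np.hstack(parts)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = X.T @ X
    if np.linalg.cond(G) > _COND_LIMIT:
        raise ValueError("collinear design (condition number above threshold)")
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    se = np.sqrt(sigma2 * np.diag(Ginv))
    return beta, se


def _prep_cov(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    cov = np.asarray(covariates, dtype=float)
    return cov[:, None] if cov.ndim == 1 else cov


def mediation_paths(
    exposure, mediator, outcome, covariates=None, standardize: bool = False
) -> PathEstimates:
    """Fit the three path regressions for one triple."""
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if standardize:
        x, m, y = zscore(x), zscore(m), zscore(y)
    cov = _prep_cov(covariates)

    Xa = _design(cov, x)
    beta_a, se_a = _ols(Xa, m)
    Xb = _design(cov, x, m)
    beta_b, se_b = _ols(Xb, y)
    beta_c, se_c = _ols(Xa, y)
    return PathEstimates(
        a=float(beta_a[-1]),
        b=float(beta_b[-1]),
        c_prime=float(beta_b[-2]),
        c_total=float(beta_c[-1]),
        se_a=float(se_a[-1]),
        se_b=float(se_b[-1]),
        se_c_prime=float(se_b[-2]),
        se_c_total=float(se_c[-1]),
        n=len(x),
    )


def _batched_ab(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, cov: np.ndarray | None, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """a- and b-path coefficients for each row of resample indices ``idx``.

    Solves the bordered normal equations batch-wise; returns (a, b, ok)
    where ok flags resamples with a well-conditioned design.
    """
    B, n = idx.shape
    xb, mb, yb = x[idx], m[idx], y[idx]
    ones = np.ones((B, n, 1))
    if cov is not None and cov.size:
        covb = cov[idx]
        Xa = np.concatenate([ones, covb, xb[:, :, None]], axis=2)
    else:
        Xa = np.concatenate([ones, xb[:, :, None]], axis=2)
    Xb = np.concatenate([Xa, mb[:, :, None]], axis=2)

    def solve_last(X, t):
        G = np.einsum("bni,bnj->bij", X, X)
        h = np.einsum("bni,bn->bi", X, t)
        ev = np.linalg.eigvalsh(G)
        ok = ev[:, 0] > ev[:, -1] / _COND_LIMIT
        Gs = np.where(ok[:, None, None], G, np.eye(X.shape[2])[None])
        beta = np.linalg.solve(Gs, h[:, :, None])[:, :, 0]
        return beta[:, -1], ok

    a, ok_a = solve_last(Xa, mb)
    b, ok_b = solve_last(Xb, yb)
    return a, b, ok_a & ok_b


def bca_interval(
    boot_estimates,
    point_estimate: float,
    jackknife_estimates=None,
    ci_level: float = 0.95,
    percentile: str = "interp",
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    ``percentile='interp'`` maps the adjusted quantiles through the
    empirical distribution with linear interpolation; ``'nearest-rank'``
    uses the ceil(alpha*B)-th order statistic.
    """
    boot = np.sort(np.asarray(boot_estimates, dtype=float))
    B = len(boot)
    if B < 2:
        raise ValueError("need at least 2 bootstrap estimates")
    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution; returning point interval")
        return float(boot[0]), float(boot[0])
    frac_below = float(np.mean(boot < point_estimate))
    if frac_below in (0.0, 1.0):
        warnings.warn("all bootstrap estimates on one side of the point estimate; clamping z0")
        z0 = float(ndtri(1.0 - 1.0 / B)) if frac_below == 1.0 else -float(ndtri(1.0 - 1.0 / B))
    else:
        z0 = float(ndtri(frac_below))
    if jackknife_estimates is None:
        accel = 0.0
    else:
        jack = np.asarray(jackknife_estimates, dtype=float)
        d = jack.mean() - jack
        denom = (d @ d) ** 1.5
        accel = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = (1.0 - ci_level) / 2.0
    out = []
    for a_level in (alpha, 1.0 - alpha):
        z = float(ndtri(a_level))
        adj = float(ndtr(z0 + (z0 + z) / (1.0 - accel * (z0 + z))))
        if percentile == "interp":
            out.append(float(np.quantile(boot, adj)))
        elif percentile == "nearest-rank":
            rank = min(B, max(1, math.ceil(adj * B)))
            out.append(float(boot[rank - 1]))
        else:
            raise ValueError(f"unknown percentile convention {percentile!r}")
    return out[0], out[1]


def bootstrap_indirect(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    standardize: bool = False,
    percentile: str = "interp",
) -> dict:
    """Case-resampling bootstrap of the indirect effect a*b with a BCa CI.

    Rank-deficient resamples are redrawn (up to 5 rounds); if more than 20%
    remain deficient the data are too degenerate and an error is raised.
    ``p_boot = 2*min(F(0), 1-F(0))`` on the bootstrap distribution.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples to bootstrap")
    if standardize:
        x, m, y = zscore(x), zscore(m), zscore(y)
    cov = _prep_cov(covariates)
    point = mediation_paths(x, m, y, cov)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    idx = rng.integers(0, n, (n_boot, n))
    a, b, ok = _batched_ab(x, m, y, cov, idx)
    n_redrawn = 0
    for _ in range(5):
        if ok.all():
            break
        bad = np.where(~ok)[0]
        n_redrawn += len(bad)
        idx_bad = rng.integers(0, n, (len(bad), n))
        a2, b2, ok2 = _batched_ab(x, m, y, cov, idx_bad)
        a[bad], b[bad], ok[bad] = a2, b2, ok2
    if (~ok).sum() > 0.2 * n_boot:
        raise ValueError("more than 20% of bootstrap resamples are rank-deficient")
    boot = (a * b)[ok]

    jack_idx = np.array([np.delete(np.arange(n), i) for i in range(n)])
    ja, jb, jok = _batched_ab(x, m, y, cov, jack_idx)
    jack = (ja * jb)[jok] if jok.any() else None

    ci_lo, ci_hi = bca_interval(boot, point.indirect, jack, ci_level, percentile)
    f0 = float(np.mean(boot < 0) + 0.5 * np.mean(boot == 0))
    p_boot = 2.0 * min(f0, 1.0 - f0)
    sign_consistency = float(np.mean(np.sign(boot) == np.sign(point.indirect))) if point.indirect != 0 else 0.0
    return {
        "paths": point,
        "indirect": point.indirect,
        "ci_lo": ci_lo,
        "ci_hi": ci_hi,
        "p_boot": p_boot,
        "boot": boot,
        "sign_consistency": sign_consistency,
        "n_boot": int(ok.sum()),
        "n_redrawn": n_redrawn,
    }


def e_value(beta_std: float, se: float | None = None, ci: tuple[float, float] | None = None,
            ci_level: float = 0.95) -> tuple[float, float]:
    """E-value for a standardized effect, via the approximate risk ratio
    RR = exp(0.91*|beta_std|); E = RR + sqrt(RR*(RR-1)).

    The CI E-value uses the bound nearer the null and is 1 when the CI
    crosses the null.  Provide either ``se`` (a symmetric normal CI is
    formed) or explicit ``ci`` bounds.
    """
    if se is not None and se < 0:
        raise ValueError("negative standard error")

    def _e(beta: float) -> float:
        rr = math.exp(0.91 * abs(beta))
        return rr + math.sqrt(rr * (rr - 1.0)) if rr > 1.0 else 1.0

    e_point = _e(beta_std)
    if ci is None:
        if se is None:
            return e_point, 1.0
        z = float(ndtri(1.0 - (1.0 - ci_level) / 2.0))
        ci = (beta_std - z * se, beta_std + z * se)
    lo, hi = ci
    if lo <= 0.0 <= hi:
        return e_point, 1.0
    near = lo if abs(lo) < abs(hi) else hi
    return e_point, _e(near)


class MediationModel:
    """Single-triple mediation model in the model/fit/results idiom.

    Parameters are the aligned exposure, mediator, and outcome vectors plus
    optional adjustment covariates.  ``standardize=True`` z-scores the three
    structural variables (covariates stay raw), so path coefficients are on
    the standardized scale used for proteome-wide comparison.
    """

    def __init__(self, outcome, exposure, mediator, covariates=None, standardize: bool = True):
        self.outcome = np.asarray(outcome, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        self.mediator = np.asarray(mediator, dtype=float)
        if not (len(self.outcome) == len(self.exposure) == len(self.mediator)):
            raise ValueError("outcome, exposure and mediator must be aligned")
        self.covariates = _prep_cov(covariates)
        self.standardize = standardize

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, exposure: str, mediator: str,
        covariates: tuple[str, ...] = (), standardize: bool = True,
    ) -> "MediationModel":
        cov = data[list(covariates)].to_numpy(dtype=float) if covariates else None
        return cls(
            data[outcome], data[exposure], data[mediator], covariates=cov,
            standardize=standardize,
        )

    def fit(
        self, n_boot: int = 1000, ci_level: float = 0.95, seed: int | None = 0,
        percentile: str = "interp",
    ) -> "MediationResults":
        res = bootstrap_indirect(
            self.exposure, self.mediator, self.outcome, self.covariates,
            n_boot=n_boot, ci_level=ci_level, seed=seed,
            standardize=self.standardize, percentile=percentile,
        )
        e_pt, e_ci = e_value(res["indirect"], ci=(res["ci_lo"], res["ci_hi"]))
        return MediationResults(
            model=self, paths=res["paths"], ci=(res["ci_lo"], res["ci_hi"]),
            p_boot=res["p_boot"], e_point=e_pt, e_ci=e_ci,
            sign_consistency=res["sign_consistency"], n_boot=res["n_boot"],
            ci_level=ci_level, seed=seed,
        )


@dataclass
class MediationResults:
    """Estimates, bootstrap uncertainty, and sensitivity diagnostics."""

    model: MediationModel
    paths: PathEstimates
    ci: tuple[float, float]
    p_boot: float
    e_point: float
    e_ci: float
    sign_consistency: float
    n_boot: int
    ci_level: float
    seed: int | None

    @property
    def indirect(self) -> float:
        return self.paths.indirect

    @property
    def params(self) -> pd.Series:
        p = self.paths
        return pd.Series(
            {"a": p.a, "b": p.b, "c_prime": p.c_prime, "c_total": p.c_total,
             "indirect": p.indirect}
        )

    @property
    def bse(self) -> pd.Series:
        p = self.paths
        return pd.Series(
            {"a": p.se_a, "b": p.se_b, "c_prime": p.se_c_prime, "c_total": p.se_c_total}
        )

    def summary(self) -> str:
        p = self.paths
        lines = [
            "Mediation (product of coefficients, BCa bootstrap)",
            "=" * 54,
            f"{'path':<10}{'coef':>10}{'se':>10}",
            f"{'a':<10}{p.a:>10.4f}{p.se_a:>10.4f}",
            f"{'b':<10}{p.b:>10.4f}{p.se_b:>10.4f}",
            f"{'c_prime':<10}{p.c_prime:>10.4f}{p.se_c_prime:>10.4f}",
            f"{'c_total':<10}{p.c_total:>10.4f}{p.se_c_total:>10.4f}",
            "-" * 54,
            f"indirect (a*b)   {p.indirect: .4f}",
            f"{int(self.ci_level * 100)}% BCa CI      [{self.ci[0]: .4f}, {self.ci[1]: .4f}]",
            f"bootstrap p      {self.p_boot:.4g}   (B={self.n_boot})",
            f"E-value          {self.e_point:.3f} (CI bound {self.e_ci:.3f})",
            f"n                {p.n}",
        ]
        return "\n".join(lines)


@dataclass
class ScreenResult:
    """Per-outcome mediation tables plus candidate and validated sets."""

    tables: dict[str, pd.DataFrame]
    candidates: list[str]
    criteria: dict
    validated: list[str] | None = None

    def table(self, outcome: str) -> pd.DataFrame:
        return self.tables[outcome]


def _screen_one_outcome(
    values: pd.DataFrame,
    exposure_id: str,
    y: np.ndarray,
    cov: np.ndarray | None,
    analytes: list[str],
    fdr: float,
    n_boot: int,
    ci_level: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(values)
    x = zscore(values[exposure_id].to_numpy(dtype=float))
    yz = zscore(y)
    M = values[analytes].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    Mz = np.where(keep, (M - M.mean(axis=0)) / np.where(keep, sd, 1.0), 0.0)

    base = [np.ones((n, 1))]
    if cov is not None and cov.size:
        base.append(cov)
    Xa = np.hstack(base + [x[:, None]])
    ka = Xa.shape[1]
    Ga_inv = np.linalg.inv(Xa.T @ Xa)
    beta_a_full = Ga_inv @ (Xa.T @ Mz)
    a_hat = beta_a_full[-1]
    resid_a = Mz - Xa @ beta_a_full
    sig2_a = (resid_a**2).sum(axis=0) / (n - ka)
    se_a = np.sqrt(sig2_a * Ga_inv[-1, -1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_a = np.where(se_a > 0, a_hat / se_a, 0.0)
    p_a = 2.0 * stats.t.sf(np.abs(t_a), n - ka)

    # b-path: bordered solve, one varying mediator column per analyte
    hy = Xa.T @ yz
    u = Xa.T @ Mz                      # (ka, P)
    s = (Mz * Mz).sum(axis=0)          # (P,)
    Gu = Ga_inv @ u
    schur = s - (u * Gu).sum(axis=0)
    my = Mz.T @ yz
    b_hat = (my - u.T @ (Ga_inv @ hy)) / schur
    g0 = Ga_inv @ (hy[:, None] - u * b_hat)   # (ka, P)
    resid_b = yz[:, None] - Xa @ g0 - Mz * b_hat
    kb = ka + 1
    sig2_b = (resid_b**2).sum(axis=0) / (n - kb)
    se_b = np.sqrt(sig2_b / schur)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = np.where(se_b > 0, b_hat / se_b, 0.0)
    p_b = 2.0 * stats.t.sf(np.abs(t_b), n - kb)

    q_a, q_b = bh_fdr(p_a), bh_fdr(p_b)
    gate = (q_a < fdr) & (q_b < fdr) & keep

    table = pd.DataFrame(
        {
            "a": a_hat, "se_a": se_a, "p_a": p_a, "q_a": q_a,
            "b": b_hat, "se_b": se_b, "p_b": p_b, "q_b": q_b,
            "indirect": a_hat * b_hat,
            "ci_lo": np.nan, "ci_hi": np.nan, "p_boot": np.nan,
            "e_value": np.nan, "e_value_ci": np.nan,
            "sign_consistency": np.nan, "n": n, "passed": False,
        },
        index=pd.Index(analytes, name="analyte_id"),
    )
    for j in np.where(gate)[0]:
        res = bootstrap_indirect(
            x, Mz[:, j], yz, cov, n_boot=n_boot, ci_level=ci_level, seed=rng,
        )
        e_pt, e_ci = e_value(res["indirect"], ci=(res["ci_lo"], res["ci_hi"]))
        aid = analytes[j]
        table.loc[aid, ["ci_lo", "ci_hi", "p_boot"]] = (
            res["ci_lo"], res["ci_hi"], res["p_boot"],
        )
        table.loc[aid, ["e_value", "e_value_ci", "sign_consistency"]] = (
            e_pt, e_ci, res["sign_consistency"],
        )
        excludes_zero = res["ci_lo"] > 0 or res["ci_hi"] < 0
        table.loc[aid, "passed"] = bool(
            excludes_zero and res["sign_consistency"] > 0.5
        )
    return table


def _cov_array(covariates, sample_ids, covariate_names) -> np.ndarray | None:
    if covariates is None:
        return None
    frame = covariates.data if isinstance(covariates, CovariateTable) else covariates
    return frame.loc[list(sample_ids), list(covariate_names)].to_numpy(dtype=float)


def mediation_screen(
    matrix: ProteinMatrix,
    exposure_id: str,
    outcomes: pd.DataFrame,
    covariates=None,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    fdr: float = 0.05,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    analytes: list[str] | None = None,
) -> ScreenResult:
    """Proteome-wide mediation screen over every outcome column.

    An analyte passes one outcome screen iff q_a < fdr, q_b < fdr, the BCa
    CI of a*b excludes 0, and the bootstrap majority shares the sign of the
    point estimate.  The candidate set is the intersection across outcomes
    with a consistent indirect-effect sign.
    """
    if exposure_id not in matrix.values.columns:
        raise KeyError(f"exposure {exposure_id!r} not in matrix")
    if exposure_id in outcomes.columns:
        raise ValueError("exposure listed among outcomes")
    if len(outcomes.columns) < 1:
        raise ValueError("need at least one outcome")
    if analytes is None:
        analytes = [a for a in matrix.analyte_ids if a != exposure_id]
    values = matrix.values.loc[outcomes.index]
    cov = _cov_array(covariates, outcomes.index, covariate_names)

    tables: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence([int(seed)])
    children = ss.spawn(len(outcomes.columns))
    for child, name in zip(children, outcomes.columns):
        rng = np.random.default_rng(child)
        tables[name] = _screen_one_outcome(
            values, exposure_id, outcomes[name].to_numpy(dtype=float), cov,
            analytes, fdr, n_boot, ci_level, rng,
        )

    candidates = []
    for aid in analytes:
        if all(t.loc[aid, "passed"] for t in tables.values()):
            signs = {np.sign(t.loc[aid, "indirect"]) for t in tables.values()}
            if len(signs) == 1:
                candidates.append(aid)
    criteria = {
        "fdr": fdr, "ci_level": ci_level, "n_boot": n_boot, "seed": seed,
        "pass_rule": "q_a<fdr & q_b<fdr & BCa CI excludes 0 & bootstrap sign majority",
        "candidate_rule": "pass all outcomes with consistent indirect sign",
    }
    return ScreenResult(tables=tables, candidates=candidates, criteria=criteria)


def validate_mediators(
    candidates: list[str],
    matrix: ProteinMatrix,
    exposure_id: str,
    composite_outcome: pd.Series,
    covariates=None,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    fdr: float = 0.05,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Re-test candidate mediators against a composite outcome; keep passers."""
    if not list(candidates):
        return [], pd.DataFrame()
    composite = pd.Series(composite_outcome)
    if not composite.index.equals(matrix.values.index):
        composite = composite.reindex(matrix.values.index)
        if composite.isna().any():
            raise ValueError("composite outcome misaligned to matrix samples")
    frame = pd.DataFrame({"composite": composite.to_numpy()}, index=matrix.values.index)
    screen = mediation_screen(
        matrix, exposure_id, frame, covariates, covariate_names,
        fdr=fdr, n_boot=n_boot, ci_level=ci_level, seed=seed,
        analytes=list(candidates),
    )
    table = screen.tables["composite"]
    return [aid for aid in candidates if table.loc[aid, "passed"]], table


def replicate_screen(
    validated: list[str],
    cohorts: list[tuple[ProteinMatrix, object, pd.Series]],
    exposure_id: str,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    fdr: float = 0.05,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Re-test a validated set in each validation cohort's composite outcome.

    Replication requires passing in every cohort; analytes absent from a
    cohort are recorded as not replicated there (reported, not fatal).
    """
    if not list(validated):
        return pd.DataFrame(), float("nan")
    results = {}
    for ci, (mat, cov, composite) in enumerate(cohorts):
        present = [aid for aid in validated if aid in mat.values.columns]
        absent = [aid for aid in validated if aid not in mat.values.columns]
        if absent:
            warnings.warn(f"analytes absent from cohort {ci}: {absent}")
        passed, _tab = validate_mediators(
            present, mat, exposure_id, composite, cov, covariate_names,
            fdr=fdr, n_boot=n_boot, ci_level=ci_level, seed=seed + ci,
        )
        col = {aid: (aid in set(passed)) for aid in validated}
        results[f"cohort{ci}"] = col
    table = pd.DataFrame(results)
    rate = float(table.all(axis=1).mean())
    return table, rate
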