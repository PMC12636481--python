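"""Synthetic CSF proteomics cohorts with planted mediation chains.

The generator emulates the structure of a multi-cohort CSF aptamer-proteomics
study: one designated exposure analyte (a fibrinogen stand-in), a set of
planted mediators carrying an exposure -> mediator -> outcome chain, planted
co-expression modules among the null analytes, a correlated 4-marker outcome
panel dominated by one latent factor, age/sex confounding of every structural
variable, a second (immunoassay-style) measurement platform with a target
cross-platform correlation, duplicate aliquots calibrated to a target
replicate CV, and MCAR missingness.

All structural equations are linear-Gaussian on the log scale; abundances are
exponentiated to the raw scale so that the documented log transform recovers
the Gaussian values exactly.  Every planted quantity is recorded in a
:class:`SyntheticTruth` so downstream stages can be scored against ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProteinMatrix, CovariateTable, OutcomePanel

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_multi_cohort",
    "generate_dual_platform",
    "inject_replicates_and_missingness",
    "mask_mcar",
    "mask_mar",
]

EXPOSURE_ID = "FGA.4907.56"
PANEL_MARKERS = ("pTau181", "NG36", "SNAP25", "GAP43")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Effects are standardized path coefficients of the linear-Gaussian
    structural model (per standard deviation of the upstream variable).
    Defaults describe a desk-scale cohort: the real study's matrices
    (~7,000 analytes, 66-1,655 donors) are emulated at reduced size; all
    counts scale up through this config.
    """

    n_samples: int = 200
    n_analytes: int = 300
    n_true_mediators: int = 5
    a_effect: float = 0.5       # exposure -> mediator
    b_effect: float = 0.5       # mediator -> latent outcome (total, split over k)
    c_prime: float = 0.2        # direct exposure -> outcome
    age_effect: float = 0.3     # confounder loading on exposure/mediators/outcome
    sex_effect: float = 0.2
    mediator_noise_sd: float = 1.5
    outcome_noise_sd: float = 0.5
    outcome_panel: tuple[str, ...] = PANEL_MARKERS
    latent_share: float = 0.85  # PC1 variance share of the marker panel
    module_spec: tuple[tuple[int, float], ...] = ((30, 0.6), (20, 0.6))
    platform_r: float = 0.8
    cv_target: float = 10.0     # replicate CV, percent
    missing_rate: float = 0.05
    n_cohorts: int = 1
    amyloid_pos_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_analytes <= 0:
            raise ValueError("n_analytes must be positive")
        if self.n_true_mediators > self.n_analytes - 1:
            raise ValueError("n_true_mediators must leave room for the exposure analyte")
        p = len(self.outcome_panel)
        if p < 2:
            raise ValueError("outcome panel needs at least 2 markers")
        if not (1.0 / p <= self.latent_share <= 1.0):
            raise ValueError(f"latent_share must be in [1/{p}, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(self.platform_r) > 1.0:
            raise ValueError("platform_r must be in [-1, 1]")
        if self.cv_target < 0:
            raise ValueError("cv_target must be nonnegative")
        if not 0.0 <= self.amyloid_pos_rate <= 1.0:
            raise ValueError("amyloid_pos_rate must be in [0, 1]")
        n_module = sum(size for size, _ in self.module_spec)
        if 1 + self.n_true_mediators + n_module > self.n_analytes:
            raise ValueError("module sizes + mediators + exposure exceed n_analytes")
        for size, r in self.module_spec:
            if not 0.0 <= r <= 1.0:
                raise ValueError("module within-correlation must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time.

    ``a`` and ``b`` are the coefficients actually used in the structural
    equations: ``a[i]`` multiplies the exposure in mediator i's equation;
    ``b[i]`` is mediator i's coefficient in the equation of each outcome
    marker (``b_effect/sqrt(k)`` rescaled onto the marker scale).
    """

    exposure_id: str
    mediator_ids: list[str]
    a: dict[str, float]
    b: dict[str, float]
    b_latent: dict[str, float]
    c_prime: float
    module_membership: dict[str, str]
    platform_pairs: list[tuple[str, str, float]]
    noise_sds: dict[str, float]
    panel_rho: float
    sd_latent_outcome: float
    marker_names: tuple[str, ...]


def _structural_sd_y(cfg: SimConfig) -> float:
    """Model-implied standard deviation of the latent outcome.

    Needed to place the marker panel on a unit-variance scale without
    empirical standardization (which would break exact coefficient
    recovery in the noiseless limit).
    """
    vc = cfg.age_effect**2 + cfg.sex_effect**2
    a, k = cfg.a_effect, cfg.n_true_mediators
    var_e = vc + 1.0
    var_m = a**2 * var_e + vc + 2 * a * vc + cfg.mediator_noise_sd**2
    cov_mm = a**2 * var_e + vc + 2 * a * vc
    cov_me = a * var_e + vc
    cov_mc = a * vc + vc
    var_s = k * var_m + k * (k - 1) * cov_mm
    cov_se = k * cov_me
    cov_sc = k * cov_mc
    bk = cfg.b_effect / math.sqrt(k) if k else 0.0
    var_y = (
        bk**2 * var_s
        + cfg.c_prime**2 * var_e
        + vc
        + cfg.outcome_noise_sd**2
        + 2 * bk * cfg.c_prime * cov_se
        + 2 * bk * cov_sc
        + 2 * cfg.c_prime * vc
    )
    return math.sqrt(var_y)


def _analyte_ids(cfg: SimConfig) -> tuple[list[str], list[str], dict[str, str]]:
    k = cfg.n_true_mediators
    mediator_ids = [f"MED{i:04d}" for i in range(k)]
    module_membership: dict[str, str] = {}
    others: list[str] = []
    idx = 0
    for m, (size, _r) in enumerate(cfg.module_spec):
        label = f"module{m + 1}"
        for _ in range(size):
            aid = f"NUL{idx:04d}"
            module_membership[aid] = label
            others.append(aid)
            idx += 1
    n_free = cfg.n_analytes - 1 - k - len(others)
    for _ in range(n_free):
        others.append(f"NUL{idx:04d}")
        idx += 1
    return mediator_ids, others, module_membership


def _stream(seed: int, tag: int, *extra: int) -> np.random.Generator:
    # distinct fixed tags per draw site: plain integer seeds pad with zeros,
    # so SeedSequence([s]) and SeedSequence([s, 0]) would collide
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag), *map(int, extra)]))


def _cohort_rng(cfg: SimConfig, cohort_index: int) -> np.random.Generator:
    return _stream(cfg.seed, 101, cohort_index)


def generate_cohort(
    config: SimConfig, cohort_index: int = 0
) -> tuple[ProteinMatrix, CovariateTable, OutcomePanel, SyntheticTruth]:
    """Generate one cohort from the linear-Gaussian structural model.

    Returns the raw-scale aptamer matrix (log10 recovers the Gaussian
    values), a covariate table, the raw-scale 4-marker outcome panel (log2
    recovers Gaussian values), and the recorded truth.
    """
    config.validate()
    rng = _cohort_rng(config, cohort_index)
    n, k = config.n_samples, config.n_true_mediators
    sample_ids = [f"C{cohort_index}S{i:04d}" for i in range(n)]

    age = rng.normal(70.0, 8.0, n)
    sex = rng.integers(0, 2, n)
    age_z = (age - 70.0) / 8.0
    sex_c = (sex - 0.5) / 0.5
    conf = config.age_effect * age_z + config.sex_effect * sex_c

    exposure = conf + rng.standard_normal(n)
    mediators = (
        config.a_effect * exposure[:, None]
        + conf[:, None]
        + config.mediator_noise_sd * rng.standard_normal((n, k))
    )

    mediator_ids, other_ids, module_membership = _analyte_ids(config)
    # planted modules: equicorrelated blocks via a shared per-sample factor
    others = np.empty((n, len(other_ids)))
    col = 0
    for size, r in config.module_spec:
        f = rng.standard_normal(n)
        eps = rng.standard_normal((n, size))
        others[:, col : col + size] = math.sqrt(r) * f[:, None] + math.sqrt(1 - r) * eps
        col += size
    n_free = len(other_ids) - col
    if n_free:
        others[:, col:] = rng.standard_normal((n, n_free))

    bk = config.b_effect / math.sqrt(k) if k else 0.0
    y_core = (
        bk * mediators.sum(axis=1)
        + config.c_prime * exposure
        + conf
        + config.outcome_noise_sd * rng.standard_normal(n)
    )
    sd_y = _structural_sd_y(config)
    factor = y_core / sd_y
    p = len(config.outcome_panel)
    rho = (p * config.latent_share - 1.0) / (p - 1.0)
    markers = math.sqrt(rho) * factor[:, None] + math.sqrt(1.0 - rho) * rng.standard_normal((n, p))

    log_values = np.column_stack([exposure, mediators, others])
    analyte_ids = [EXPOSURE_ID] + mediator_ids + other_ids
    values = pd.DataFrame(np.power(10.0, log_values), index=sample_ids, columns=analyte_ids)

    analyte_meta = pd.DataFrame(
        {
            "analyte_id": analyte_ids,
            "target": [aid.split(".")[0] for aid in analyte_ids],
            "gene": [aid.split(".")[0] for aid in analyte_ids],
            "col_check": "PASS",
        }
    ).set_index("analyte_id")
    matrix = ProteinMatrix(
        values=values,
        analyte_meta=analyte_meta,
        row_check=pd.Series("PASS", index=sample_ids),
        platform="aptamer",
        transform="raw",
    )

    # clinical outcomes tied to the latent factor (white-matter integrity
    # declines and processing speed slows with the planted pathology)
    covariates = CovariateTable(
        pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "cohort": f"cohort{cohort_index}",
                "amyloid_status": np.where(
                    rng.random(n) < config.amyloid_pos_rate, "positive", "negative"
                ),
                "processing_speed_ms": 900.0 + 80.0 * (0.4 * factor + rng.standard_normal(n)),
                "fa_slf": 0.45 - 0.02 * (0.4 * factor + rng.standard_normal(n)),
            },
            index=sample_ids,
        )
    )

    panel = OutcomePanel(
        values=pd.DataFrame(
            np.power(2.0, markers), index=sample_ids, columns=list(config.outcome_panel)
        ),
        transform="raw",
    )

    b_marker = bk * math.sqrt(rho) / sd_y
    truth = SyntheticTruth(
        exposure_id=EXPOSURE_ID,
        mediator_ids=list(mediator_ids),
        a={mid: config.a_effect for mid in mediator_ids},
        b={mid: b_marker for mid in mediator_ids},
        b_latent={mid: bk for mid in mediator_ids},
        c_prime=config.c_prime,
        module_membership=module_membership,
        platform_pairs=default_platform_pairs(config),
        noise_sds={
            "mediator": config.mediator_noise_sd,
            "outcome": config.outcome_noise_sd,
            "marker_idiosyncratic": math.sqrt(1.0 - rho),
        },
        panel_rho=rho,
        sd_latent_outcome=sd_y,
        marker_names=tuple(config.outcome_panel),
    )
    return matrix, covariates, panel, truth


def default_platform_pairs(config: SimConfig) -> list[tuple[str, str, float]]:
    """Default immunoassay/aptamer pairs: the exposure plus first mediators."""
    mediator_ids = [f"MED{i:04d}" for i in range(config.n_true_mediators)]
    pairs = [("FGA_elisa", EXPOSURE_ID, config.platform_r)]
    for i, mid in enumerate(mediator_ids[:4]):
        pairs.append((f"IA_{mid}", mid, config.platform_r))
    return pairs


def generate_multi_cohort(
    config: SimConfig,
) -> list[tuple[ProteinMatrix, CovariateTable, OutcomePanel, SyntheticTruth]]:
    """Independent cohorts sharing one set of structural coefficients.

    Each cohort has its own samples and noise draws; the recorded truth
    (mediator identities and path coefficients) is identical across cohorts.
    """
    if config.n_cohorts < 1:
        raise ValueError("n_cohorts must be at least 1")
    return [generate_cohort(config, i) for i in range(config.n_cohorts)]


def generate_dual_platform(
    matrix: ProteinMatrix,
    platform_pairs: list[tuple[str, str, float]],
    seed: int = 0,
) -> ProteinMatrix:
    """Immunoassay-style re-measurement of a subset of analytes.

    Each pair (immunoassay name, aptamer id, r) yields a second-platform
    column whose log2 values correlate with the z-scored log10 aptamer
    values at r (exactly r in expectation; empirically converging as n
    grows).  Output is on the raw concentration scale with a log2
    transform convention.
    """
    rng = _stream(seed, 202)
    log_vals = np.log10(matrix.values.to_numpy(dtype=float)) if matrix.transform == "raw" else matrix.values.to_numpy(dtype=float)
    cols = {}
    for name, aid, r in platform_pairs:
        if abs(r) > 1:
            raise ValueError(f"platform correlation {r} outside [-1, 1]")
        if aid not in matrix.values.columns:
            raise KeyError(f"analyte {aid!r} not in matrix")
        z = log_vals[:, matrix.values.columns.get_loc(aid)]
        z = (z - z.mean()) / z.std(ddof=0)
        noise = rng.standard_normal(len(z))
        cols[name] = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * noise
    values = pd.DataFrame(cols, index=matrix.values.index)
    meta = pd.DataFrame(
        {
            "analyte_id": list(cols),
            "target": [name.split("_")[0] for name in cols],
            "gene": [name.split("_")[0] for name in cols],
            "col_check": "PASS",
        }
    ).set_index("analyte_id")
    return ProteinMatrix(
        values=np.power(2.0, values),
        analyte_meta=meta,
        row_check=pd.Series("PASS", index=values.index),
        platform="immunoassay",
        transform="raw",
    )


def inject_replicates_and_missingness(
    matrix: ProteinMatrix,
    cv_target: float,
    missing_rate: float,
    seed: int = 0,
    n_duplicates: int | None = None,
) -> tuple[ProteinMatrix, list[tuple[str, str]], pd.DataFrame]:
    """Append duplicate aliquots and mask cells completely at random.

    Duplicates multiply the original raw values by lognormal measurement
    error with log-sd ``(cv_target/100)*sqrt(pi)``, calibrated so the
    expected two-aliquot sample CV equals ``cv_target`` percent.  Missing
    cells are drawn Bernoulli(missing_rate) independently of all values
    (MCAR by construction).  Returns the augmented matrix, the duplicate
    pairs, and the boolean missingness mask.
    """
    if cv_target < 0:
        raise ValueError("cv_target must be nonnegative")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _stream(seed, 303)
    n = len(matrix.values)
    if n_duplicates is None:
        n_duplicates = max(1, min(20, n // 2))
    dup_idx = rng.choice(n, size=n_duplicates, replace=False)
    dup_ids = [matrix.values.index[i] for i in sorted(dup_idx)]
    sigma = (cv_target / 100.0) * math.sqrt(math.pi)
    dup_rows = {}
    for sid in dup_ids:
        noise = np.exp(rng.normal(0.0, sigma, matrix.values.shape[1])) if sigma > 0 else 1.0
        dup_rows[f"{sid}_rep"] = matrix.values.loc[sid].to_numpy() * noise
    dup_frame = pd.DataFrame.from_dict(dup_rows, orient="index", columns=matrix.values.columns)
    values = pd.concat([matrix.values, dup_frame])
    mask = pd.DataFrame(
        rng.random(values.shape) < missing_rate, index=values.index, columns=values.columns
    )
    values = values.mask(mask)
    out = ProteinMatrix(
        values=values,
        analyte_meta=matrix.analyte_meta,
        row_check=pd.concat(
            [matrix.row_check, pd.Series("PASS", index=list(dup_rows))]
        ),
        platform=matrix.platform,
        transform=matrix.transform,
    )
    pairs = [(sid, f"{sid}_rep") for sid in dup_ids]
    return out, pairs, mask


def mask_mcar(table: pd.DataFrame, missing_rate: float, seed: int = 0) -> pd.DataFrame:
    """Mask cells Bernoulli(missing_rate), independent of every value."""
    rng = _stream(seed, 404)
    mask = rng.random(table.shape) < missing_rate
    return table.mask(pd.DataFrame(mask, index=table.index, columns=table.columns))


def mask_mar(
    table: pd.DataFrame,
    driver: str,
    target: str,
    missing_rate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Missing-at-random scenario: target cells go missing preferentially
    where the (always-observed) driver column is high.

    Used to check the power of the MCAR test: missingness depends on
    observed data, so pattern means differ and the test should reject.
    """
    rng = _stream(seed, 505)
    ranks = table[driver].rank(pct=True).to_numpy()
    # piecewise probability: cells in the top driver tertile are 4x as
    # likely to be missing; overall rate kept at missing_rate
    p = np.where(ranks > 2.0 / 3.0, 4.0, 0.5)
    p = p * missing_rate / p.mean()
    out = table.copy()
    out.loc[rng.random(len(table)) < p, target] = np.nan
    return out
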