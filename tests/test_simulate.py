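"""Generator properties: determinism, structural identification, calibration."""

import numpy as np
import pandas as pd
import pytest

from proteomediate.qc import log_transform, replicate_cv
from proteomediate.simulate import (
    SimConfig,
    generate_cohort,
    generate_dual_platform,
    generate_multi_cohort,
    inject_replicates_and_missingness,
)

NOCONF = dict(age_effect=0.0, sex_effect=0.0, module_spec=())


def test_seeded_determinism_bit_identical():
    cfg = SimConfig(n_samples=50, n_analytes=40, seed=9, module_spec=((10, 0.5),))
    m1, c1, p1, t1 = generate_cohort(cfg)
    m2, c2, p2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(m1.values, m2.values)
    pd.testing.assert_frame_equal(c1.data, c2.data)
    pd.testing.assert_frame_equal(p1.values, p2.values)
    assert t1.mediator_ids == t2.mediator_ids


def test_global_null_exposure_outcome_uncorrelated():
    """With all paths and confounders zeroed, exposure-outcome correlation
    is centered at zero with sampling-noise magnitude."""
    n = 120
    rs = []
    for seed in range(200):
        cfg = SimConfig(n_samples=n, n_analytes=10, n_true_mediators=2,
                        a_effect=0, b_effect=0, c_prime=0, seed=seed, **NOCONF)
        matrix, _, panel, truth = generate_cohort(cfg)
        x = np.log10(matrix.values[truth.exposure_id])
        for marker in panel.marker_names:
            rs.append(np.corrcoef(x, np.log2(panel.values[marker]))[0, 1])
    assert abs(np.mean(np.abs(rs)) - 0) < 3 / np.sqrt(n)


def test_noiseless_a_path_identification():
    """With zero mediator noise the adjusted a-path regression recovers the
    planted coefficient exactly."""
    cfg = SimConfig(n_samples=80, n_analytes=10, n_true_mediators=2,
                    a_effect=0.5, b_effect=0.5, mediator_noise_sd=0.0,
                    module_spec=(), seed=1)
    matrix, cov, _, truth = generate_cohort(cfg)
    logm = log_transform(matrix, 10)
    X = np.column_stack([np.ones(cfg.n_samples), cov.data["age"], cov.data["sex"],
                         logm.values[truth.exposure_id]])
    for mid in truth.mediator_ids:
        beta, *_ = np.linalg.lstsq(X, logm.values[mid].to_numpy(), rcond=None)
        assert beta[-1] == pytest.approx(0.5, abs=1e-6)


def test_noiseless_joint_b_and_c_prime_identification():
    """With zero latent-outcome noise and a pure-factor panel, the joint
    regression of a marker on all mediators plus exposure recovers the
    recorded marker-scale coefficients."""
    cfg = SimConfig(n_samples=100, n_analytes=10, n_true_mediators=3,
                    outcome_noise_sd=0.0, latent_share=1.0, module_spec=(), seed=2)
    matrix, cov, panel, truth = generate_cohort(cfg)
    logm = log_transform(matrix, 10)
    y = np.log2(panel.values[truth.marker_names[0]]).to_numpy()
    X = np.column_stack(
        [np.ones(len(y))]
        + [logm.values[mid] for mid in truth.mediator_ids]
        + [logm.values[truth.exposure_id], cov.data["age"], cov.data["sex"]]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    expected_b = truth.b[truth.mediator_ids[0]]
    expected_cp = truth.c_prime * np.sqrt(truth.panel_rho) / truth.sd_latent_outcome
    for j in range(len(truth.mediator_ids)):
        assert beta[1 + j] == pytest.approx(expected_b, abs=1e-6)
    assert beta[1 + len(truth.mediator_ids)] == pytest.approx(expected_cp, abs=1e-6)


def test_multi_cohort_shares_truth_with_independent_noise():
    cfg = SimConfig(n_samples=40, n_analytes=20, n_cohorts=3, module_spec=(), seed=5)
    cohorts = generate_multi_cohort(cfg)
    assert len(cohorts) == 3
    ids = {tuple(t.mediator_ids) for _, _, _, t in cohorts}
    assert len(ids) == 1
    v0, v1 = cohorts[0][0].values.to_numpy(), cohorts[1][0].values.to_numpy()
    assert not np.any(v0 == v1)


def test_multi_cohort_rejects_zero_cohorts():
    cfg = SimConfig(n_cohorts=0)
    with pytest.raises(ValueError):
        generate_multi_cohort(cfg)


def test_truth_completeness(small_cohort):
    matrix, _, _, truth = small_cohort
    assert truth.exposure_id not in truth.mediator_ids
    for mid in truth.mediator_ids:
        assert mid in matrix.values.columns
        assert mid in truth.a and mid in truth.b


@pytest.mark.parametrize("r", [1.0, 0.0])
def test_dual_platform_extremes(r):
    cfg = SimConfig(n_samples=300, n_analytes=20, module_spec=(), seed=3)
    matrix, _, _, truth = generate_cohort(cfg)
    if r == 1.0:
        dp = generate_dual_platform(matrix, [("FGA_elisa", truth.exposure_id, 1.0)], seed=0)
        z1 = np.log10(matrix.values[truth.exposure_id])
        z2 = np.log2(dp.values["FGA_elisa"])
        rho = pd.Series(z1).corr(pd.Series(z2.to_numpy(), index=z1.index), method="spearman")
        assert rho == pytest.approx(1.0)
    else:
        rs = []
        for seed in range(100):
            dp = generate_dual_platform(matrix, [("X", truth.exposure_id, 0.0)], seed=seed)
            rs.append(abs(np.corrcoef(
                np.log10(matrix.values[truth.exposure_id]), np.log2(dp.values["X"])
            )[0, 1]))
        assert np.mean(rs) < 3 / np.sqrt(cfg.n_samples)


def test_dual_platform_target_correlation_band():
    """Empirical r lies within the Fisher-z sampling band around the target."""
    hits = 0
    for seed in range(200):
        cfg = SimConfig(n_samples=500, n_analytes=30, module_spec=(), seed=seed)
        matrix, _, _, truth = generate_cohort(cfg)
        dp = generate_dual_platform(matrix, [("X", truth.exposure_id, 0.8)], seed=seed)
        r = np.corrcoef(np.log10(matrix.values[truth.exposure_id]),
                        np.log2(dp.values["X"]))[0, 1]
        hits += abs(r - 0.8) <= 0.06
    assert hits / 200 >= 0.95


def test_dual_platform_rejects_invalid_r(small_cohort):
    matrix, _, _, truth = small_cohort
    with pytest.raises(ValueError):
        generate_dual_platform(matrix, [("X", truth.exposure_id, 1.2)], seed=0)


def test_replicates_identical_at_zero_cv(small_cohort):
    matrix, _, _, _ = small_cohort
    aug, pairs, mask = inject_replicates_and_missingness(matrix, 0.0, 0.0, seed=0)
    assert not mask.to_numpy().any()
    for orig, dup in pairs:
        np.testing.assert_array_equal(aug.values.loc[orig], aug.values.loc[dup])


def test_replicate_cv_calibrated_to_target():
    """Median per-analyte CV tracks the requested 10% within 2 points."""
    medians = []
    for seed in range(5):
        cfg = SimConfig(n_samples=100, n_analytes=200, seed=seed)
        matrix, _, _, _ = generate_cohort(cfg)
        aug, pairs, _ = inject_replicates_and_missingness(matrix, 10.0, 0.0, seed=seed)
        cv, _ = replicate_cv(aug, pairs)
        medians.append(cv.median())
    assert all(abs(m - 10.0) < 2.0 for m in medians)


def test_missingness_mask_reported_and_mcar(small_cohort):
    matrix, _, _, _ = small_cohort
    aug, _, mask = inject_replicates_and_missingness(matrix, 0.0, 0.2, seed=7)
    assert aug.values.isna().equals(mask)
    assert 0.1 < mask.to_numpy().mean() < 0.3
    with pytest.raises(ValueError):
        inject_replicates_and_missingness(matrix, 0.0, 1.0, seed=0)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(n_samples=0).validate()
    with pytest.raises(ValueError):
        SimConfig(n_analytes=3, n_true_mediators=5).validate()
    with pytest.raises(ValueError):
        SimConfig(missing_rate=1.0).validate()
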