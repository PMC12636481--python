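"""Mediation paths, BCa bootstrap, E-values, and the screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteomediate.mediation import (
    MediationModel,
    bca_interval,
    bootstrap_indirect,
    e_value,
    mediation_paths,
    mediation_screen,
    replicate_screen,
    validate_mediators,
)
from proteomediate.qc import log_transform
from proteomediate.simulate import SimConfig, generate_cohort, generate_multi_cohort

X4, M4 = [0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 5.0, 5.0]
Y4 = [3.0 * v for v in M4]


def test_worked_example_paths():
    p = mediation_paths(X4, M4, Y4)
    assert p.a == pytest.approx(1.6)
    assert p.b == pytest.approx(3.0)
    assert p.c_prime == pytest.approx(0.0, abs=1e-12)
    assert p.c_total == pytest.approx(4.8)
    assert p.indirect == pytest.approx(4.8)


def test_orthogonal_mediator_zero_indirect():
    x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
    m = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])
    y = np.array([0.5, 1.0, -0.3, 0.2, 0.9, -0.1])
    p = mediation_paths(x, m, y)
    assert p.a == pytest.approx(0.0, abs=1e-12)
    assert p.indirect == pytest.approx(0.0, abs=1e-12)


def test_identical_mediator_and_exposure_errors():
    x = np.arange(10.0)
    with pytest.raises(ValueError, match="collinear"):
        mediation_paths(x, x, 2 * x)


def test_total_effect_decomposition_identity():
    """c = c' + a*b exactly on arbitrary data with shared covariates."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = 40
        cov = rng.standard_normal((n, 2))
        x, m, y = rng.standard_normal((3, n))
        p = mediation_paths(x, m, y, covariates=cov)
        assert p.c_total == pytest.approx(p.c_prime + p.indirect, abs=1e-8)


def test_bca_nearest_rank_hand_example():
    lo, hi = bca_interval(np.arange(1.0, 101.0), 50.5, None, 0.95,
                          percentile="nearest-rank")
    assert (lo, hi) == (3.0, 98.0)


def test_bca_reduces_to_percentile_when_symmetric():
    rng = np.random.default_rng(1)
    boot = rng.standard_normal(4001)
    boot = np.concatenate([boot, -boot])  # exactly symmetric around 0
    lo, hi = bca_interval(boot, 0.0, None, 0.95)
    assert lo == pytest.approx(np.quantile(boot, 0.025), abs=1e-9)
    assert hi == pytest.approx(np.quantile(boot, 0.975), abs=1e-9)


def test_bca_degenerate_distribution_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        lo, hi = bca_interval(np.full(200, 4.8), 4.8)
    assert lo == hi == 4.8


def test_bootstrap_noiseless_replication_concentrates_on_point():
    """Noiseless 20-row replication of the worked example: the point
    estimate is exact and the bootstrap interval brackets it.  (Resampled
    a-paths still vary because the mediator is not affine in the exposure,
    so the interval is tight but not degenerate.)"""
    x = np.tile(X4, 5)
    m = np.tile(M4, 5)
    y = 3.0 * m
    res = bootstrap_indirect(x, m, y, n_boot=200, seed=0)
    assert res["indirect"] == pytest.approx(4.8, abs=1e-12)
    assert res["ci_lo"] <= 4.8 <= res["ci_hi"]
    assert res["p_boot"] <= 0.01


def test_bootstrap_seeded_determinism():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(60)
    m = 0.4 * x + rng.standard_normal(60)
    y = 0.4 * m + rng.standard_normal(60)
    r1 = bootstrap_indirect(x, m, y, n_boot=300, seed=11)
    r2 = bootstrap_indirect(x, m, y, n_boot=300, seed=11)
    assert (r1["ci_lo"], r1["ci_hi"], r1["p_boot"]) == (r2["ci_lo"], r2["ci_hi"], r2["p_boot"])


def test_bootstrap_coverage_sanity():
    """95% BCa CI covers the true indirect effect at roughly nominal rate
    (narrow Monte-Carlo check; the full-depth check runs in acceptance)."""
    rng = np.random.default_rng(3)
    cover = 0
    N = 150
    for _ in range(N):
        n = 100
        x = rng.standard_normal(n)
        m = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        y = 0.3 * m + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        res = bootstrap_indirect(x, m, y, n_boot=300, seed=rng)
        cover += res["ci_lo"] <= 0.09 <= res["ci_hi"]
    assert 0.88 <= cover / N <= 1.0


@pytest.mark.parametrize(
    "beta,ci,expected",
    [
        (0.0, None, 1.0),
        (np.log(2) / 0.91, None, 2.0 + np.sqrt(2.0)),
    ],
)
def test_e_value_closed_forms(beta, ci, expected):
    e_pt, _ = e_value(beta, ci=ci)
    assert e_pt == pytest.approx(expected, abs=1e-9)


def test_e_value_ci_crossing_null_is_one():
    _, e_ci = e_value(0.3, ci=(-0.1, 0.7))
    assert e_ci == 1.0
    with pytest.raises(ValueError):
        e_value(0.3, se=-1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=-3, max_value=3))
def test_e_value_at_least_one(beta):
    e_pt, _ = e_value(beta)
    assert e_pt >= 1.0


def test_model_results_summary_and_identity():
    rng = np.random.default_rng(4)
    n = 120
    age = rng.normal(70, 8, n)
    x = 0.2 * (age - 70) / 8 + rng.standard_normal(n)
    m = 0.5 * x + rng.standard_normal(n)
    y = 0.5 * m + 0.2 * x + rng.standard_normal(n)
    data = pd.DataFrame({"fib": x, "med": m, "ptau": y, "age": age,
                         "sex": rng.integers(0, 2, n)})
    model = MediationModel.from_dataframe(data, outcome="ptau", exposure="fib",
                                          mediator="med", covariates=("age", "sex"))
    res = model.fit(n_boot=300, seed=5)
    assert res.paths.c_total == pytest.approx(res.paths.c_prime + res.indirect, abs=1e-8)
    text = res.summary()
    assert "indirect" in text and "BCa" in text and "E-value" in text
    assert res.params["indirect"] == pytest.approx(res.indirect)


def _screen_inputs(cfg):
    matrix, cov, panel, truth = generate_cohort(cfg)
    return log_transform(matrix, 10), cov, np.log2(panel.values), truth


def test_screen_recovers_planted_mediators_and_sets_nest():
    # near-zero latent-outcome noise forces recovery of all planted mediators
    cfg = SimConfig(n_samples=300, n_analytes=100, n_true_mediators=5,
                    outcome_noise_sd=0.05, latent_share=0.99,
                    module_spec=((20, 0.6),), seed=17)
    m, cov, outcomes, truth = _screen_inputs(cfg)
    screen = mediation_screen(m, truth.exposure_id, outcomes, cov, n_boot=200, seed=17)
    assert set(screen.candidates) == set(truth.mediator_ids)
    assert truth.exposure_id not in screen.candidates
    composite = outcomes.mean(axis=1)
    validated, _ = validate_mediators(screen.candidates, m, truth.exposure_id,
                                      composite, cov, n_boot=200, seed=17)
    assert set(validated) <= set(screen.candidates)
    assert len(validated) >= 4


def test_screen_single_outcome_equals_intersection_of_one():
    cfg = SimConfig(n_samples=200, n_analytes=50, n_true_mediators=2,
                    module_spec=(), seed=21)
    m, cov, outcomes, truth = _screen_inputs(cfg)
    single = outcomes[[outcomes.columns[0]]]
    screen = mediation_screen(m, truth.exposure_id, single, cov, n_boot=200, seed=21)
    passed = screen.tables[outcomes.columns[0]]
    assert set(screen.candidates) == set(passed.index[passed["passed"]])


def test_screen_rejects_exposure_as_outcome(small_cohort):
    matrix, cov, panel, truth = small_cohort
    m = log_transform(matrix, 10)
    bad = np.log2(panel.values).copy()
    bad[truth.exposure_id] = m.values[truth.exposure_id]
    with pytest.raises(ValueError, match="exposure"):
        mediation_screen(m, truth.exposure_id, bad, cov, n_boot=50, seed=0)


def test_screen_seeded_determinism():
    cfg = SimConfig(n_samples=150, n_analytes=40, n_true_mediators=2,
                    module_spec=(), seed=8)
    m, cov, outcomes, truth = _screen_inputs(cfg)
    s1 = mediation_screen(m, truth.exposure_id, outcomes, cov, n_boot=100, seed=3)
    s2 = mediation_screen(m, truth.exposure_id, outcomes, cov, n_boot=100, seed=3)
    assert s1.candidates == s2.candidates
    for k in s1.tables:
        pd.testing.assert_frame_equal(s1.tables[k], s2.tables[k])


def test_validate_empty_candidates_and_noise_composite():
    cfg = SimConfig(n_samples=200, n_analytes=60, n_true_mediators=3,
                    module_spec=(), seed=13)
    m, cov, outcomes, truth = _screen_inputs(cfg)
    validated, _ = validate_mediators([], m, truth.exposure_id,
                                      outcomes.mean(axis=1), cov, seed=0)
    assert validated == []
    # composite replaced by pure noise: planted mediators do not validate
    hits = 0
    for s in range(10):
        noise = pd.Series(np.random.default_rng(s).standard_normal(len(outcomes)),
                          index=outcomes.index)
        v, _ = validate_mediators(truth.mediator_ids, m, truth.exposure_id,
                                  noise, cov, n_boot=100, seed=s)
        hits += len(v) > 0
    assert hits <= 1


def test_replicate_screen_two_cohorts_and_single_cohort_rate():
    cfg = SimConfig(n_samples=300, n_analytes=80, n_true_mediators=5,
                    n_cohorts=3, module_spec=(), seed=19)
    cohorts = generate_multi_cohort(cfg)
    prepared = []
    for matrix, cov, panel, truth in cohorts[1:]:
        prepared.append((log_transform(matrix, 10), cov,
                         np.log2(panel.values).mean(axis=1)))
    truth = cohorts[0][3]
    table, rate = replicate_screen(truth.mediator_ids, prepared, truth.exposure_id,
                                   n_boot=200, seed=19)
    assert rate >= 0.9
    t1, r1 = replicate_screen(truth.mediator_ids, prepared[:1], truth.exposure_id,
                              n_boot=200, seed=19)
    assert r1 == pytest.approx(t1.all(axis=1).mean())
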