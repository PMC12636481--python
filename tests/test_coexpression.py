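"""Signed network construction, TOM, module detection, preservation."""

import numpy as np
import pandas as pd
import pytest

from proteomediate.coexpression import (
    correlation_preservation,
    detect_modules,
    module_eigengene_kme,
    module_preservation,
    scale_free_fit,
    signed_adjacency,
    soft_threshold_scan,
    tom_similarity,
)


def _block_values(rng, n, sizes, within_r, n_noise=0):
    cols = []
    for size in sizes:
        f = rng.standard_normal(n)
        cols.append(np.sqrt(within_r) * f[:, None]
                    + np.sqrt(1 - within_r) * rng.standard_normal((n, size)))
    if n_noise:
        cols.append(rng.standard_normal((n, n_noise)))
    arr = np.hstack(cols)
    names = [f"a{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=names)


def test_scale_free_fit_exact_power_law():
    k = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])
    assert scale_free_fit(k) == pytest.approx(1.0)


def test_scale_free_fit_anti_power_law_nonpositive():
    k = np.repeat([1.0, 2.0, 4.0, 8.0], [1, 2, 4, 8])
    assert scale_free_fit(k) <= 0.0
    with pytest.raises(ValueError):
        scale_free_fit(np.ones(10))


def test_soft_threshold_first_hit_rule():
    rng = np.random.default_rng(0)
    values = _block_values(rng, 150, [15, 15], 0.7, n_noise=10)
    scan, chosen = soft_threshold_scan(values, powers=range(15, 27))
    hits = scan.index[scan["signed_r2"] >= 0.8]
    assert chosen == (int(hits[0]) if len(hits) else int(scan["signed_r2"].idxmax()))
    assert chosen in range(15, 27)


@pytest.mark.parametrize("cor,power,expected", [(1.0, 7, 1.0), (-1.0, 7, 0.0),
                                                (0.0, 12, 0.5**12)])
def test_signed_adjacency_values(cor, power, expected):
    c = np.array([[1.0, cor], [cor, 1.0]])
    a = signed_adjacency(c, power)
    assert a[0, 1] == pytest.approx(expected)
    assert a[0, 0] == 0.0
    with pytest.raises(ValueError):
        signed_adjacency(np.array([[1.0, 1.5], [1.5, 1.0]]), power)


def test_tom_hand_example_and_limits():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    tom = tom_similarity(a)
    assert tom[0, 1] == pytest.approx(0.5)
    assert tom[0, 2] == pytest.approx(0.0)
    full = np.ones((5, 5)) - np.eye(5)
    assert np.allclose(tom_similarity(full)[np.triu_indices(5, 1)], 1.0)
    empty = np.zeros((4, 4))
    assert np.allclose(tom_similarity(empty)[np.triu_indices(4, 1)], 0.0)
    with pytest.raises(ValueError, match="symmetric"):
        tom_similarity(np.array([[0.0, 0.3], [0.1, 0.0]]))


def test_tom_bounds_on_random_adjacency():
    rng = np.random.default_rng(1)
    a = rng.random((20, 20))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    tom = tom_similarity(a)
    assert np.all(tom >= -1e-12) and np.all(tom <= 1 + 1e-12)


def _detect_from_corr(corr, min_size=5):
    tom = tom_similarity(signed_adjacency(corr, 6))
    return detect_modules(tom, [f"a{j}" for j in range(len(corr))], min_size=min_size)


def test_two_block_planted_structure_recovered_exactly():
    corr = np.eye(20)
    corr[:10, :10] = 0.9
    corr[10:, 10:] = 0.9
    np.fill_diagonal(corr, 1.0)
    labels = _detect_from_corr(corr)
    groups = [set(labels.index[labels == m]) for m in ("module1", "module2")]
    assert {frozenset(g) for g in groups} == {
        frozenset(f"a{j}" for j in range(10)),
        frozenset(f"a{j}" for j in range(10, 20)),
    }


def test_identity_correlation_all_unassigned():
    labels = _detect_from_corr(np.eye(12))
    assert (labels == "unassigned").all()


def test_small_block_below_min_size_unassigned():
    corr = np.eye(12)
    corr[:4, :4] = 0.9
    np.fill_diagonal(corr, 1.0)
    labels = _detect_from_corr(corr, min_size=5)
    assert (labels == "unassigned").all()


def test_module_labels_invariant_to_permutation():
    rng = np.random.default_rng(2)
    values = _block_values(rng, 200, [10, 10], 0.7, n_noise=5)
    corr = np.corrcoef(values.to_numpy(), rowvar=False)
    labels = _detect_from_corr(corr)
    perm = rng.permutation(len(corr))
    corr_p = corr[np.ix_(perm, perm)]
    tom_p = tom_similarity(signed_adjacency(corr_p, 6))
    labels_p = detect_modules(tom_p, [f"a{j}" for j in perm])
    for orig, permuted in zip([f"a{j}" for j in perm], labels_p.index):
        assert (labels[orig] == "unassigned") == (labels_p[permuted] == "unassigned")


def test_planted_module_recovery_jaccard():
    """Jaccard >= 0.9 against planted blocks at within-r 0.6, n=200."""
    rng = np.random.default_rng(3)
    values = _block_values(rng, 200, [10, 10], 0.6, n_noise=20)
    corr = np.corrcoef(values.to_numpy(), rowvar=False)
    labels = _detect_from_corr(corr)
    planted = [set(f"a{j}" for j in range(10)), set(f"a{j}" for j in range(10, 20))]
    detected = [set(labels.index[labels == m]) for m in labels.unique()
                if m != "unassigned"]
    scores = []
    for block in planted:
        best = max((len(block & d) / len(block | d) for d in detected), default=0.0)
        scores.append(best)
    assert min(scores) >= 0.9


def test_eigengene_and_kme():
    rng = np.random.default_rng(4)
    z = rng.standard_normal(50)
    z -= z.mean()
    ortho = rng.standard_normal(50)
    ortho -= ortho.mean()
    ortho -= ortho @ z / (z @ z) * z  # centered and orthogonal to centered z
    values = pd.DataFrame({
        "m1": 2.0 * z + 1.0, "m2": 0.5 * z - 3.0, "other": ortho,
    })
    labels = pd.Series({"m1": "module1", "m2": "module1", "other": "unassigned"})
    eg, kme = module_eigengene_kme(values, labels)
    zstd = (z - z.mean()) / z.std()
    np.testing.assert_allclose(np.abs(np.corrcoef(eg["module1"], zstd)[0, 1]), 1.0)
    assert kme.loc["m1", "module1"] == pytest.approx(1.0)
    assert kme.loc["m2", "module1"] == pytest.approx(1.0)
    assert kme.loc["other", "module1"] == pytest.approx(0.0, abs=1e-10)


def test_eigengene_kme_factor_model_matches_theory():
    """kME of members in a factor model concentrates near sqrt(share)."""
    lam = 0.7
    kmes = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        values = _block_values(rng, 150, [10], lam)
        labels = pd.Series("module1", index=values.columns)
        _, kme = module_eigengene_kme(values, labels)
        kmes.append(kme["module1"].mean())
    assert abs(np.mean(kmes) - np.sqrt(lam)) < 0.05


def test_preservation_identity_scaling_and_null():
    rng = np.random.default_rng(5)
    values = _block_values(rng, 100, [10], 0.7)
    members = list(values.columns)
    assert module_preservation(members, values, values) == pytest.approx(1.0)
    corr = np.corrcoef(values.to_numpy(), rowvar=False)
    assert correlation_preservation(corr, 0.5 * corr) == pytest.approx(1.0)
    scores = []
    for seed in range(100):
        r = np.random.default_rng(1000 + seed)
        noise = pd.DataFrame(r.standard_normal((100, 20)),
                             columns=[f"a{j}" for j in range(20)])
        block = _block_values(np.random.default_rng(2000 + seed), 100, [20], 0.6)
        scores.append(module_preservation(list(block.columns), block, noise))
    assert abs(np.mean(scores)) < 0.1
    with pytest.raises(ValueError):
        module_preservation(members[:2], values, values)
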