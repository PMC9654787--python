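"""Quadratic intensity model: extraction, fitting, prediction, inference."""

import numpy as np
import pandas as pd
import pytest

from endocoloc import (
    MultiChannelImage,
    bootstrap_coefficient_se,
    correlation_report,
    effective_mask,
    extract_pairs,
    find_islands,
    fit_quadratic,
    pool_pairs,
    predict_pfak,
)
from conftest import make_image

# Published coefficients of the quadratic probe-to-pFAK coupling.
COEF = (125.86, 0.346, -2.99e-5)


def _pairs(x, y, source="s"):
    return pd.DataFrame({"n_aie": x, "n_pfak": y, "source_id": source, "island_id": pd.NA})


def _quad(x):
    a0, a1, a2 = COEF
    return a0 + a1 * x + a2 * x**2


def simulate_pairs(n=10_000, noise_sd=20.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 4000, n)
    y = _quad(x) + rng.normal(0, noise_sd, n)
    return _pairs(x, y)


# ------------------------------------------------------------- extraction

def test_extract_singleton_and_empty(rng):
    img = make_image(rng, shape=(4, 4), p_zero=0.0)
    img.probe[2, 2], img.pfak[2, 2] = 100, 160
    flags = np.zeros((4, 4), dtype=bool)
    flags[2, 2] = True
    mask = effective_mask(img, 0)
    mask.flags = flags
    pairs = extract_pairs(img, mask)
    assert len(pairs) == 1
    assert (pairs.n_aie[0], pairs.n_pfak[0]) == (100, 160)

    mask.flags = np.zeros((4, 4), dtype=bool)
    assert len(extract_pairs(img, mask)) == 0


def test_extract_matches_brute_force_and_annotates_islands(rng):
    img = make_image(rng, shape=(16, 16))
    mask = effective_mask(img, 0)
    islands = find_islands(mask, 8)
    pairs = extract_pairs(img, mask, islands)
    expected = [
        (int(img.probe[r, c]), int(img.pfak[r, c]))
        for r in range(16) for c in range(16) if mask.flags[r, c]
    ]
    assert list(zip(pairs.n_aie, pairs.n_pfak)) == expected
    label = islands.label_image()
    for _, row in pairs.iterrows():
        assert row.island_id >= 1
    assert pairs.island_id.tolist() == [
        int(label[r, c]) for r in range(16) for c in range(16) if mask.flags[r, c]
    ]


def test_pool_pairs_counts_identity_and_duplicates():
    a = _pairs([1, 2], [3, 4], "imgA")
    b = _pairs([], [], "imgB").iloc[0:0]
    c = _pairs([5, 6, 7, 8, 9], np.arange(5), "imgA")  # duplicate source_id kept
    pooled = pool_pairs([a, b, c])
    assert len(pooled) == 7
    assert (pooled.source_id == "imgA").sum() == 7
    single = pool_pairs([a])
    pd.testing.assert_frame_equal(single, a)
    assert len(pool_pairs([])) == 0


# ---------------------------------------------------------------- fitting

def test_noise_free_fit_recovers_published_coefficients_exactly():
    x = np.arange(0, 4001, 500, dtype=float)
    fit = fit_quadratic(_pairs(x, _quad(x)))
    assert fit.a0 == pytest.approx(COEF[0], rel=1e-6)
    assert fit.a1 == pytest.approx(COEF[1], rel=1e-6)
    assert fit.a2 == pytest.approx(COEF[2], rel=1e-6)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)


def test_three_points_interpolated_exactly():
    x = np.array([1.0, 2.0, 5.0])
    y = 3 - 2 * x + 0.5 * x**2
    fit = fit_quadratic(_pairs(x, y))
    assert (fit.a0, fit.a1, fit.a2) == pytest.approx((3, -2, 0.5))
    assert fit.r2 == pytest.approx(1.0)


def test_degree_one_fit():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_quadratic(_pairs(x, 2 + 5 * x), degree=1)
    assert (fit.a0, fit.a1, fit.a2) == pytest.approx((2.0, 5.0, 0.0))


def test_rank_deficient_design_rejected():
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_quadratic(_pairs([1, 1, 2, 2], [5, 6, 7, 8]))
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_quadratic(_pairs([1, 2], [5, 6]))


def test_residuals_orthogonal_to_design():
    pairs = simulate_pairs(n=500, seed=4)
    fit = fit_quadratic(pairs)
    x = pairs.n_aie.to_numpy()
    resid = pairs.n_pfak.to_numpy() - predict_pfak(fit, x)
    scale = np.abs(pairs.n_pfak).sum()
    for col in (np.ones_like(x), x, x**2):
        assert abs(resid @ col) / (scale * np.abs(col).max()) < 1e-9


def test_fit_invariant_to_pair_order():
    pairs = simulate_pairs(n=200, seed=9)
    shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    f1, f2 = fit_quadratic(pairs), fit_quadratic(shuffled)
    grid = np.linspace(0, 4000, 7)
    np.testing.assert_allclose(predict_pfak(f1, grid), predict_pfak(f2, grid), rtol=1e-9)


# ------------------------------------------------------------- prediction

def test_predict_at_zero_returns_intercept():
    fit = fit_quadratic(_pairs([0.0, 500, 1000, 2000], _quad(np.array([0.0, 500, 1000, 2000]))))
    assert predict_pfak(fit, 0) == pytest.approx(125.86, abs=1e-9)


def test_predict_direct_evaluation_and_zero_model():
    from endocoloc import IntensityFit

    fit = IntensityFit(a0=125.86, a1=0.346, a2=-2.99e-5, degree=2,
                       n_points=0, r2=1.0, pearson_r=None, residual_sd=0.0)
    assert predict_pfak(fit, 1000) == pytest.approx(441.96)
    zero = IntensityFit(a0=0, a1=0, a2=0, degree=2, n_points=0, r2=1.0,
                        pearson_r=None, residual_sd=0.0)
    assert predict_pfak(zero, 1234.5) == 0.0
    np.testing.assert_allclose(predict_pfak(zero, np.arange(5.0)), np.zeros(5))


# -------------------------------------------------------------- inference

def test_noisy_recovery_within_three_bootstrap_se():
    pairs = simulate_pairs(seed=11)
    fit = fit_quadratic(pairs)
    se = bootstrap_coefficient_se(pairs, n_boot=200, seed=11)
    for est, gen, s in zip((fit.a0, fit.a1, fit.a2), COEF, se):
        assert abs(est - gen) < 3 * s


def test_parameter_recovery_and_bootstrap_coverage():
    """Over 50 seeded replicates, mean coefficient estimates land within 1%
    of the generating values and 3-SE bootstrap intervals cover them in at
    least 90% of replicates."""
    estimates, covered = [], np.zeros(3)
    n_rep = 50
    for rep in range(n_rep):
        pairs = simulate_pairs(seed=1000 + rep)
        fit = fit_quadratic(pairs)
        se = bootstrap_coefficient_se(pairs, n_boot=120, seed=1000 + rep)
        est = np.array([fit.a0, fit.a1, fit.a2])
        estimates.append(est)
        covered += np.abs(est - COEF) <= 3 * se
    mean_est = np.mean(estimates, axis=0)
    np.testing.assert_allclose(mean_est, COEF, rtol=0.01)
    assert np.all(covered / n_rep >= 0.90)


def test_correlation_report_perfect_line():
    x = np.arange(10, dtype=float)
    pairs = _pairs(x, 2 * x + 1)
    fit = fit_quadratic(pairs)
    rep = correlation_report(pairs, fit, n_permutations=499, seed=0)
    assert rep["pearson_r"] == pytest.approx(1.0)
    assert rep["permutation_p"] <= 1 / 500 + 1e-12
    assert rep["n_points"] == 10


def test_correlation_report_constant_response_flagged():
    pairs = _pairs([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
    fit = fit_quadratic(pairs)
    rep = correlation_report(pairs, fit, n_permutations=99, seed=0)
    assert rep["pearson_r"] is None and rep["permutation_p"] is None


def test_correlation_signal_beats_shuffled_null():
    pairs = simulate_pairs(n=200, seed=5)
    fit = fit_quadratic(pairs)
    p_signal = correlation_report(pairs, fit, n_permutations=999, seed=5)["permutation_p"]
    rng = np.random.default_rng(6)
    shuffled = _pairs(pairs.n_aie.to_numpy(), rng.permutation(pairs.n_pfak.to_numpy()))
    p_null = correlation_report(shuffled, fit_quadratic(shuffled),
                                n_permutations=999, seed=6)["permutation_p"]
    assert p_signal < p_null


def test_correlation_report_needs_three_pairs():
    with pytest.raises(ValueError, match="3 pairs"):
        correlation_report(_pairs([1, 2], [1, 2]), None)
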