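"""Logistic models for death, ROC/AUC duality, and the DeLong test."""

import numpy as np
import pytest

from comoscore import SeparationError, ValidationError
from comoscore.io import Cohort, EpisodeRecord
from comoscore.mortality import (
    _fit_design,
    build_design,
    delong_auc_test,
    delong_variance,
    fit_logistic,
    predict_probability,
    roc_curve,
)
from comoscore.scoring import StrataAssignment, assign_strata
from comoscore.simulate import simulate_strata_cohort


def _cohort(deaths, ages=None):
    n = len(deaths)
    ages = ages if ages is not None else [60] * n
    eps = [
        EpisodeRecord(f"c{i}", ages[i], "male", bool(deaths[i]), 1, ("J189",))
        for i in range(n)
    ]
    return Cohort(episodes=eps)


def test_two_by_two_or_equals_cross_product_ratio():
    # exposure x outcome counts: a=30 (x=1,y=1), b=20 (x=1,y=0), c=10, d=40
    a, b, c, d = 30, 20, 10, 40
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    X = np.column_stack([np.ones_like(x), x])
    fit = _fit_design(X, y, ["intercept", "exposure"], "ordinal")
    assert np.exp(fit.coefficients[1]) == pytest.approx(a * d / (b * c), rel=1e-8)


def test_score_equations_hold_at_convergence(rng):
    n = 2000
    strata = rng.integers(1, 5, n)
    age = np.where(rng.random(n) < 0.5, 80, 60)
    lp = -3 + 0.5 * strata + 0.7 * (age > 72)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    X, names = build_design(strata, age, 72, "ordinal", "toy")
    fit = _fit_design(X, y, names, "ordinal")
    p = predict_probability(fit, X)
    assert np.max(np.abs(X.T @ (y - p))) < 1e-6


def test_null_covariate_ci_covers_one(rng):
    n = 3000
    strata = rng.integers(1, 5, n)
    y = (rng.random(n) < 0.2).astype(float)  # independent of strata
    X, names = build_design(strata, np.full(n, 60), 72, "ordinal", "toy")
    # drop the constant age column to keep the design full rank
    fit = _fit_design(X[:, :2], y, names[:2], "ordinal")
    row = fit.or_table.iloc[0]
    assert row["ci_low"] < 1.0 < row["ci_high"]


def test_one_class_outcome_raises():
    cohort = _cohort([0, 0, 0, 0])
    sa = StrataAssignment("x", (1, 2, 3), np.array([1, 2, 3, 4]), None)
    with pytest.raises(ValidationError):
        fit_logistic(cohort, sa)


def test_complete_separation_detected():
    n = 400
    strata = np.tile([1, 2, 3, 4], n // 4)
    y = (strata > 2).astype(float)
    X, names = build_design(strata, np.full(n, 60), 72, "ordinal", "toy")
    with pytest.raises(SeparationError):
        _fit_design(X[:, :2], y, names[:2], "ordinal")


def test_categorical_fit_reports_reference_stratum(rng):
    cohort, strata = simulate_strata_cohort(4000, 0.6, 0.5, -3.0, seed=9)
    sa = assign_strata(strata, "toy")
    fit = fit_logistic(cohort, sa, "categorical", age_cut=72)
    ref = fit.or_table.iloc[0]
    assert "reference" in ref["covariate"]
    assert ref["or"] == 1.0 and np.isnan(ref["ci_low"])
    assert len(fit.or_table) == 5  # reference + strata 2-4 + age


def test_parameter_recovery_single_replicate():
    cohort, strata = simulate_strata_cohort(20000, 0.8, 0.8, -4.0, seed=3)
    sa = StrataAssignment("toy", (2, 3, 4), strata, None)
    fit = fit_logistic(cohort, sa, "ordinal", age_cut=72)
    est = fit.coefficients
    assert est[1] == pytest.approx(0.8, abs=0.1)
    assert est[2] == pytest.approx(0.8, abs=0.15)


def test_predict_probability_basics():
    fit = _fit_design(
        np.column_stack([np.ones(10), np.arange(10.0)]),
        np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 1.0]),
        ["intercept", "x"], "ordinal",
    )
    # hand-built coefficients: logit 0 at x = 3 for (intercept -3, slope 1)
    fit.coefficients = np.array([-3.0, 1.0])
    assert predict_probability(fit, np.array([[1.0, 3.0]]))[0] == pytest.approx(0.5)
    fit.coefficients = np.array([0.0, 0.0])
    assert np.allclose(predict_probability(fit, np.column_stack([np.ones(5), np.arange(5.0)])), 0.5)


def test_intercept_only_fit_gives_observed_rate():
    y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0.0])
    fit = _fit_design(np.ones((10, 1)), y, ["intercept"], "ordinal")
    p = predict_probability(fit, np.ones((1, 1)))[0]
    assert p == pytest.approx(y.mean(), abs=1e-8)


def test_predict_dimension_mismatch():
    fit = _fit_design(np.ones((10, 1)), np.array([1, 0] * 5, dtype=float), ["intercept"], "o")
    with pytest.raises(ValidationError):
        predict_probability(fit, np.ones((3, 2)))


# ---------------------------------------------------------------- ROC / AUC

def test_roc_perfect_separation():
    r = roc_curve([3, 2, 1, 0], [1, 1, 0, 0])
    assert r.auc == pytest.approx(1.0)
    assert tuple(r.points[0]) == (0.0, 0.0) and tuple(r.points[-1]) == (1.0, 1.0)


def test_roc_constant_scores_half():
    r = roc_curve([5, 5, 5, 5], [1, 0, 1, 0])
    assert r.auc == pytest.approx(0.5)


def test_roc_known_value():
    r = roc_curve([3, 1, 2, 0], [1, 1, 0, 0])
    assert r.auc == pytest.approx(0.75)


def test_roc_matches_pairwise_oracle(rng):
    """AUC equals the fraction of (positive, negative) pairs correctly
    ordered, with half credit for ties — computed by brute force."""
    for _ in range(20):
        n = 40
        scores = rng.integers(0, 6, n).astype(float)
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            continue
        pos, neg = scores[y], scores[~y]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        expected = wins / (pos.size * neg.size)
        assert roc_curve(scores, y).auc == pytest.approx(expected, abs=1e-12)


def test_roc_matches_sklearn(rng):
    sk = pytest.importorskip("sklearn.metrics")
    scores = rng.standard_normal(500)
    y = rng.random(500) < 0.3
    assert roc_curve(scores, y).auc == pytest.approx(
        sk.roc_auc_score(y, scores), abs=1e-12
    )


def test_roc_points_monotone(rng):
    scores = rng.integers(0, 4, 200).astype(float)
    y = rng.random(200) < 0.3
    pts = roc_curve(scores, y).points
    assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


def test_auc_invariant_under_increasing_transform(rng):
    scores = rng.standard_normal(300)
    y = rng.random(300) < 0.3
    a = roc_curve(scores, y).auc
    b = roc_curve(np.exp(scores), y).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_roc_one_class_raises():
    with pytest.raises(ValidationError):
        roc_curve([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------- DeLong

def test_delong_self_comparison_degenerate(rng):
    scores = rng.standard_normal(200)
    y = rng.random(200) < 0.3
    cmp = delong_auc_test(scores, scores.copy(), y)
    assert cmp.auc_diff == 0.0
    assert cmp.z == 0.0 and cmp.p == 1.0


def test_delong_variance_close_to_hanley_mcneil_on_tiefree_toy(rng):
    # Hanley-McNeil closed form assuming exponential-like score distributions
    scores = rng.standard_normal(300)
    y = np.zeros(300, dtype=bool)
    y[:100] = True
    scores[y] += 1.0
    v = delong_variance(scores, y)
    auc = roc_curve(scores, y).auc
    m, n = 100, 200
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    hm = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    assert v == pytest.approx(hm, rel=0.25)


def test_delong_variance_matches_bootstrap_small_toy(rng):
    pos = np.array([3.1, 2.5, 4.0, 1.2, 2.2, 3.3, 2.8, 1.9, 3.7, 2.0])
    neg = np.array([1.1, 0.5, 2.0, 1.5, 0.2, 2.3, 1.8, 0.9, 1.7, 1.0])
    scores = np.concatenate([pos, neg])
    y = np.array([True] * 10 + [False] * 10)
    v = delong_variance(scores, y)
    B = 10000
    bp = pos[rng.integers(0, 10, (B, 10))]
    bn = neg[rng.integers(0, 10, (B, 10))]
    aucs = (bp[:, :, None] > bn[:, None, :]).mean(axis=(1, 2)) + 0.5 * (
        bp[:, :, None] == bn[:, None, :]
    ).mean(axis=(1, 2))
    assert v == pytest.approx(aucs.var(ddof=1), rel=0.15)


def test_delong_unpaired_inputs_rejected(rng):
    with pytest.raises(ValidationError):
        delong_auc_test(np.ones(5), np.ones(6), np.array([1, 0, 1, 0, 1], dtype=bool))


def test_delong_detects_a_real_difference(rng):
    n = 2000
    y = rng.random(n) < 0.2
    good = y.astype(float) + rng.standard_normal(n) * 0.7
    bad = rng.standard_normal(n)
    cmp = delong_auc_test(good, bad, y, pair=("good", "bad"))
    assert cmp.auc_diff > 0.2
    assert cmp.p < 1e-6
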