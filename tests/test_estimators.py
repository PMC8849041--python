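"""Estimator correctness against closed forms and matrix/IRLS/IV oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from adheresim import (Method, TrialData, compute_stabilized_weights, estimate,
                       estimate_baseline_adjusted, estimate_ipw_pp,
                       estimate_naive, estimate_pyaz, estimate_two_stage,
                       fit_linear_rd, get_scenario, simulate_trial)

from conftest import small_trial_from_counts


# ---------------------------------------------------------------- linear fit

def test_single_regressor_equals_difference_in_means():
    y = np.array([1, 1, 0, 0, 1, 0, 0, 0], float)
    z = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    fit = fit_linear_rd(y, np.column_stack([np.ones(8), z]))
    assert fit.ok
    # mean(Y | Z=1) - mean(Y | Z=0) = 2/4 - 1/4
    assert fit.coefficients[1] == pytest.approx(0.25)


def test_constant_outcome_zero_slope_zero_se():
    y = np.ones(20)
    z = np.tile([0.0, 1.0], 10)
    fit = fit_linear_rd(y, np.column_stack([np.ones(20), z]))
    assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)
    assert fit.robust_cov[1, 1] == pytest.approx(0.0, abs=1e-12)


def test_sandwich_equals_explicit_matrix_formula():
    """HC0 covariance equals (X'X)^-1 X' diag(e^2) X (X'X)^-1 directly."""
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
    y = rng.binomial(1, 0.4, 50).astype(float)
    fit = fit_linear_rd(y, X)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    sandwich = bread @ (X.T * e**2) @ X @ bread
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
    np.testing.assert_allclose(fit.robust_cov, sandwich, atol=1e-10)


def test_weighted_sandwich_equals_explicit_formula():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(60), rng.normal(size=60)])
    y = rng.binomial(1, 0.5, 60).astype(float)
    w = rng.uniform(0.5, 2.0, 60)
    fit = fit_linear_rd(y, X, weights=w)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    e = y - X @ beta
    bread = np.linalg.inv(XtW @ X)
    sandwich = bread @ (XtW * e**2) @ XtW.T @ bread
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
    np.testing.assert_allclose(fit.robust_cov, sandwich, atol=1e-10)


def test_rank_deficiency_flagged_not_raised():
    X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    fit = fit_linear_rd(np.zeros(10), X)
    assert not fit.ok and "rank" in fit.message


# ------------------------------------------------------------ naive methods

def test_naive_methods_zero_outcome(toy_trial):
    toy_trial.Y = np.zeros_like(toy_trial.Y)
    for m in (Method.ITT, Method.NAIVE_PP, Method.NAIVE_AT):
        r = estimate_naive(toy_trial, m)
        assert r.converged and r.rd == pytest.approx(0.0, abs=1e-12)


def test_perfect_adherence_collapses_naive_methods():
    rng = np.random.default_rng(3)
    Z = rng.binomial(1, 0.5, 300).astype(np.int8)
    Y = rng.binomial(1, 0.2 + 0.4 * Z).astype(np.int8)
    d = TrialData(Z=Z, A=Z.copy(), Y=Y)
    rds = [estimate_naive(d, m).rd
           for m in (Method.ITT, Method.NAIVE_PP, Method.NAIVE_AT)]
    assert rds[0] == pytest.approx(rds[1], abs=1e-12)
    assert rds[0] == pytest.approx(rds[2], abs=1e-12)


def test_naive_pp_equals_count_arithmetic():
    """On an expanded 2x2x2 count table, per-protocol RD equals the hand
    difference of event proportions among adherent subjects."""
    counts = {(1, 1, 1): 30, (1, 1, 0): 70,   # adherent treated
              (1, 0, 1): 5, (1, 0, 0): 15,    # deviating treated arm
              (0, 0, 1): 10, (0, 0, 0): 90,   # adherent control
              (0, 1, 1): 6, (0, 1, 0): 4}     # deviating control arm
    d = small_trial_from_counts(counts)
    r = estimate_naive(d, Method.NAIVE_PP)
    hand = 30 / 100 - 10 / 100
    assert r.rd == pytest.approx(hand, abs=1e-12)
    assert r.n_used == 200


def test_single_arm_fails_gracefully():
    d = TrialData(Z=np.ones(50, np.int8), A=np.ones(50, np.int8),
                  Y=np.zeros(50, np.int8))
    r = estimate_naive(d, Method.ITT)
    assert not r.converged


# -------------------------------------------------------- adjusted methods

def test_adjusted_matches_normal_equations(s1_trial):
    d = s1_trial
    keep = d.Z == d.A
    X = np.column_stack([np.ones(keep.sum()), d.Z[keep], d.L1[keep], d.L2[keep]])
    beta = np.linalg.solve(X.T @ X, X.T @ d.Y[keep])
    r = estimate_baseline_adjusted(d, Method.B_PP)
    assert r.rd == pytest.approx(beta[1], abs=1e-10)


def test_adjusted_agrees_with_unadjusted_under_independence():
    """With covariates independent of everything, adjustment leaves the
    collapsible risk difference unchanged up to sampling noise."""
    rng = np.random.default_rng(4)
    n = 4000
    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    A = np.where(rng.random(n) < 0.9, Z, 1 - Z).astype(np.int8)
    Y = rng.binomial(1, 0.3 + 0.2 * A).astype(np.int8)
    d = TrialData(Z=Z, A=A, Y=Y, L1=rng.normal(size=n),
                  L2=rng.binomial(1, 0.4, n).astype(np.int8))
    u = estimate_naive(d, Method.ITT).rd
    a = estimate_baseline_adjusted(d, Method.B_ITT)
    assert a.rd == pytest.approx(u, abs=3 * a.se)


def test_adjusted_methods_require_covariates():
    d = simulate_trial(get_scenario("A1", 1), 300, 0)
    with pytest.raises(ValueError, match="no l1/l2"):
        estimate_baseline_adjusted(d, Method.B_PP)
    with pytest.raises(ValueError, match="no l1/l2"):
        estimate_two_stage(d, "TSLS", "both")


def test_constant_outcome_adjusted_rd_zero(s1_trial):
    import dataclasses
    d = dataclasses.replace(s1_trial, Y=np.ones(s1_trial.n, np.int8))
    r = estimate_baseline_adjusted(d, Method.B_ITT)
    assert r.rd == pytest.approx(0.0, abs=1e-10)


# --------------------------------------------------------------- IP weights

def test_weights_match_irls_oracle():
    """Weights equal the stabilized formula applied to logistic fitted
    probabilities computed by an independent likelihood optimizer."""
    d = simulate_trial(get_scenario("S1", 3), 600, 77)
    aw = compute_stabilized_weights(d)
    assert aw.ok

    keep = d.Z == d.A
    a = d.A[keep].astype(float)
    X = np.column_stack([np.ones(keep.sum()), d.L1[keep], d.L2[keep]])

    def nll(beta):
        eta = X @ beta
        return np.sum(np.logaddexp(0, eta) - a * eta)

    res = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
    p = expit(X @ res.x)
    marg = a.mean()
    w = marg * a / p + (1 - marg) * (1 - a) / (1 - p)
    np.testing.assert_allclose(aw.weights, w, rtol=1e-5)


def test_intercept_only_truth_gives_unit_weights():
    """When adherence is unrelated to the covariates, stabilized weights
    are near 1 for everyone."""
    rng = np.random.default_rng(6)
    n = 5000
    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    A = np.where(rng.random(n) < 0.7, Z, 1 - Z).astype(np.int8)
    d = TrialData(Z=Z, A=A, Y=rng.binomial(1, 0.3, n).astype(np.int8),
                  L1=rng.normal(size=n), L2=rng.binomial(1, 0.5, n).astype(np.int8))
    aw = compute_stabilized_weights(d)
    assert np.all(np.abs(aw.weights - 1) < 0.15)
    assert abs(aw.weights.mean() - 1) < 0.05


def test_stabilized_weights_mean_near_one(s1_trial, s2_trial):
    for d in (s1_trial, s2_trial):
        aw = compute_stabilized_weights(d)
        assert aw.ok
        assert abs(aw.weights.mean() - 1) < 0.05


def test_ipw_reduces_to_naive_pp_with_unit_weights():
    rng = np.random.default_rng(7)
    n = 3000
    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    A = np.where(rng.random(n) < 0.8, Z, 1 - Z).astype(np.int8)
    d = TrialData(Z=Z, A=A, Y=rng.binomial(1, 0.2 + 0.2 * A).astype(np.int8),
                  L1=rng.normal(size=n), L2=rng.binomial(1, 0.5, n).astype(np.int8))
    ipw = estimate_ipw_pp(d)
    npp = estimate_naive(d, Method.NAIVE_PP)
    assert ipw.rd == pytest.approx(npp.rd, abs=0.01)


# ---------------------------------------------------------------- two-stage

def test_tsls_equals_wald_ratio(toy_trial):
    """Binary-instrument two-stage least squares without covariates is the
    classic Wald ratio of arm differences."""
    d = toy_trial
    itt = d.Y[d.Z == 1].mean() - d.Y[d.Z == 0].mean()
    comp = d.A[d.Z == 1].mean() - d.A[d.Z == 0].mean()
    r = estimate_two_stage(d, "TSLS", "none")
    assert r.converged
    assert r.rd == pytest.approx(itt / comp, rel=1e-6)


def test_tsri_equals_tsls_without_covariates(toy_trial):
    a = estimate_two_stage(toy_trial, "TSLS", "none")
    b = estimate_two_stage(toy_trial, "TSRI", "none")
    assert a.rd == pytest.approx(b.rd, rel=1e-8)


def test_tsls_matches_iv_moment_oracle():
    """Covariate-free 2SLS equals cov(Z, Y)/cov(Z, A), the just-identified
    instrumental-variable moment solution."""
    d = simulate_trial(get_scenario("A1", 21), 500, 99)
    r = estimate_two_stage(d, "TSLS", "none")
    oracle = np.cov(d.Z, d.Y)[0, 1] / np.cov(d.Z, d.A)[0, 1]
    assert r.rd == pytest.approx(oracle, rel=1e-6)


def test_first_stage_separation_flagged():
    rng = np.random.default_rng(8)
    Z = rng.binomial(1, 0.5, 200).astype(np.int8)
    d = TrialData(Z=Z, A=Z.copy(), Y=rng.binomial(1, 0.3, 200).astype(np.int8))
    r = estimate_two_stage(d, "TSLS", "none")
    assert not r.converged


def test_constant_instrument_flagged():
    d = TrialData(Z=np.ones(100, np.int8), A=np.ones(100, np.int8),
                  Y=np.zeros(100, np.int8))
    r = estimate_two_stage(d, "TSRI", "none")
    assert not r.converged


def test_dispatcher_covers_all_methods(s1_trial):
    for m in Method:
        r = estimate(s1_trial, m)
        assert r.method is m
        assert r.converged
        assert r.ci_lower <= r.rd <= r.ci_upper
        assert r.ci_upper - r.ci_lower == pytest.approx(2 * 1.959963984540054 * r.se)


def test_estimates_invariant_to_subject_order(s1_trial):
    rng = np.random.default_rng(9)
    perm = rng.permutation(s1_trial.n)
    d = TrialData(Z=s1_trial.Z[perm], A=s1_trial.A[perm], Y=s1_trial.Y[perm],
                  L1=s1_trial.L1[perm], L2=s1_trial.L2[perm])
    for m in (Method.ITT, Method.B_PP, Method.IPW_PP, Method.TSLS_BOTH,
              Method.TSRI_BOTH):
        assert estimate(d, m).rd == pytest.approx(estimate(s1_trial, m).rd,
                                                  abs=1e-8)


# -------------------------------------------------- observed probabilities

def test_pyaz_singletons():
    d = TrialData(Z=np.array([1, 0], np.int8), A=np.array([1, 0], np.int8),
                  Y=np.array([1, 0], np.int8))
    p = estimate_pyaz(d).p
    assert p[1, 1, 1] == 1 and p[0, 0, 0] == 1
    assert p.sum() == 2


def test_pyaz_uniform_counts():
    counts = {(z, a, y): 10 for z in (0, 1) for a in (0, 1) for y in (0, 1)}
    p = estimate_pyaz(small_trial_from_counts(counts)).p
    np.testing.assert_allclose(p, 0.25)


def test_pyaz_matches_hand_tabulation():
    rng = np.random.default_rng(10)
    n = 200
    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    A = rng.binomial(1, 0.5, n).astype(np.int8)
    Y = rng.binomial(1, 0.5, n).astype(np.int8)
    d = TrialData(Z=Z, A=A, Y=Y)
    p = estimate_pyaz(d).p
    for z in (0, 1):
        arm = Z == z
        for a in (0, 1):
            for y in (0, 1):
                assert p[y, a, z] == pytest.approx(
                    np.sum(arm & (A == a) & (Y == y)) / arm.sum())
    np.testing.assert_allclose(p.sum(axis=(0, 1)), 1.0, atol=1e-12)


def test_pyaz_empty_arm_rejected():
    d = TrialData(Z=np.ones(10, np.int8), A=np.ones(10, np.int8),
                  Y=np.zeros(10, np.int8))
    with pytest.raises(ValueError, match="empty"):
        estimate_pyaz(d)
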