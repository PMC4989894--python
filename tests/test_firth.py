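"""Firth and standard logistic regression against closed forms, a dense-grid
oracle, statsmodels, and constructed separated designs."""

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from phewaskit.firth import (
    DIVERGENCE_BOUND,
    SEPARATION_COMPLETE,
    SEPARATION_NONE,
    SEPARATION_QUASI,
    detect_separation,
    fit_firth,
    fit_standard_logistic,
    penalized_loglik,
)


def grid_maximize(X, y, k, lo=-6.0, hi=6.0, points=13, rounds=7):
    """Independent oracle: coarse-to-fine grid search of the penalized
    likelihood, never touching the Newton solver."""
    centers = np.zeros(k)
    width = hi - lo
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - width / 2, c + width / 2, points) for c in centers]
        best_val = -np.inf
        for beta in itertools.product(*axes):
            val = penalized_loglik(X, y, np.array(beta))
            if val > best_val:
                best_val, best = val, np.array(beta)
        centers = best
        width = width / (points - 1) * 2.5
    return best


@pytest.mark.parametrize("n,k", [(10, 5), (10, 0), (7, 7), (23, 4), (50, 49)])
def test_intercept_only_closed_form(n, k):
    """Intercept-only Firth fit equals the add-half estimator (k+1/2)/(n+1)."""
    X = np.ones((n, 1))
    y = np.r_[np.ones(k), np.zeros(n - k)]
    fit = fit_firth(X, y, tol=1e-10)
    assert abs(expit(fit.beta[0]) - (k + 0.5) / (n + 1)) < 1e-8


def test_two_by_two_closed_form(rng):
    """Saturated 2x2 slope equals the classic add-1/2 log odds ratio."""
    for _ in range(10):
        a, b, c, d = rng.integers(1, 30, size=4)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        X = np.column_stack([np.ones(x.size), x])
        fit = fit_firth(X, y, tol=1e-10)
        expected = math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
        assert fit.beta[1] == pytest.approx(expected, abs=1e-6)


def test_newton_matches_grid_oracle(rng):
    """Newton solution agrees with dense grid maximization of l*."""
    for trial in range(3):
        n = int(rng.integers(12, 30))
        k = int(rng.integers(1, 3))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_firth(X, y, tol=1e-10)
        oracle = grid_maximize(X, y, k + 1)
        assert np.max(np.abs(fit.beta - oracle)) < 1e-4


def test_complete_separation_handling():
    """Threshold-separable toy: detector says complete, standard logistic
    refuses to converge, Firth returns finite estimates and SEs."""
    X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
    y = np.r_[np.zeros(10), np.ones(10)]
    assert detect_separation(X, y) == SEPARATION_COMPLETE
    std = fit_standard_logistic(X, y)
    assert not std.converged
    assert std.separation_flag == SEPARATION_QUASI  # "separation suspected"
    firth = fit_firth(X, y)
    assert firth.converged
    assert np.isfinite(firth.beta).all() and np.isfinite(firth.se).all()


def test_quasi_separation_zero_case_cell(rng):
    """A covariate level with zero cases (the classic site/platform cell
    problem) is quasi-separation: Firth still yields finite inference."""
    z = np.r_[np.ones(30), np.zeros(70)]
    y = np.r_[np.zeros(30), (rng.random(70) < 0.5).astype(float)]
    X = np.column_stack([np.ones(100), z])
    assert detect_separation(X, y) == SEPARATION_QUASI
    firth = fit_firth(X, y)
    assert np.isfinite(firth.beta).all() and np.isfinite(firth.se).all()


def test_overlapping_classes_no_separation(rng):
    X = np.column_stack([np.ones(200), rng.normal(size=200)])
    y = (rng.random(200) < 0.5).astype(float)
    assert detect_separation(X, y) == SEPARATION_NONE


def test_standard_logistic_matches_statsmodels(rng):
    """On well-conditioned data the hand-rolled IRLS equals statsmodels."""
    n = 500
    X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n), rng.normal(size=n)])
    y = (rng.random(n) < expit(-0.5 + 0.4 * X[:, 1] - 0.3 * X[:, 2])).astype(float)
    ours = fit_standard_logistic(X, y, tol=1e-8)
    ref = sm.Logit(y, X).fit(disp=0)
    assert ours.converged
    np.testing.assert_allclose(ours.beta, ref.params, atol=1e-5)
    np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-4)


def test_firth_bias_correction_shrinks_with_n(rng):
    """|Firth - ML| is O(1/n): the gap shrinks as the sample grows."""
    gaps = []
    for n in (200, 2000, 20000):
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < expit(-1.0 + 0.5 * g)).astype(float)
        X = np.column_stack([np.ones(n), g])
        gap = abs(fit_firth(X, y).beta[1] - fit_standard_logistic(X, y).beta[1])
        gaps.append(gap)
    assert gaps[2] < gaps[0]
    assert gaps[2] < 1e-3


def test_penalized_loglik_nondecreasing_trace(rng):
    X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
    y = (rng.random(60) < 0.3).astype(float)
    fit = fit_firth(X, y)
    trace = np.array(fit.loglik_trace)
    assert (np.diff(trace) >= -1e-9).all()


def test_intercept_symmetry_standard():
    """Balanced intercept-only ML fit is exactly zero."""
    X = np.ones((10, 1))
    y = np.r_[np.ones(5), np.zeros(5)]
    fit = fit_standard_logistic(X, y)
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)


def test_rejects_nonbinary_response():
    with pytest.raises(ValueError, match="binary"):
        fit_firth(np.ones((3, 1)), np.array([0.0, 0.5, 1.0]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_firth_estimates_always_finite(seed):
    """The Jeffreys penalty guarantees an interior maximum: estimates and
    SEs are finite on arbitrary (even separated) small datasets."""
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 25))
    X = np.column_stack([np.ones(n), r.binomial(2, 0.3, n)])
    y = (r.random(n) < 0.4).astype(float)
    fit = fit_firth(X, y)
    assert np.isfinite(fit.beta).all()
    assert np.isfinite(fit.se).all()
    assert np.isfinite(fit.loglik)


def test_divergence_bound_is_scale_invariant(rng):
    """The separation heuristic standardizes columns, so rescaling a
    covariate does not change the diagnosis."""
    X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)] * 1000.0])
    y = np.r_[np.zeros(10), np.ones(10)]
    std = fit_standard_logistic(X, y)
    assert not std.converged
    assert std.separation_flag == SEPARATION_QUASI
    assert DIVERGENCE_BOUND == 15.0
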