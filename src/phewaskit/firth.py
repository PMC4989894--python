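"""Firth penalized-likelihood logistic regression and separation diagnostics.

Ordinary maximum-likelihood logistic regression breaks down under complete
or quasi-complete separation — when some direction in covariate space
(perfectly or almost perfectly) predicts the outcome, the likelihood is
monotone and the MLE diverges. This is routine in EHR association sweeps:
rare diagnoses crossed with site/platform dummies frequently yield cells
with zero cases or zero controls.

Firth's bias-reduction penalty (a Jeffreys prior on the coefficients) fixes
both problems at once: the penalized likelihood

    l*(β) = l(β) + ½ log det I(β),      I(β) = X' W X,  W = diag(π(1-π))

always has a finite interior maximum, and the estimator removes the O(1/n)
bias of the MLE. The maximizer solves the modified score equations

    U*_j = Σ_i (y_i − π_i + h_i (½ − π_i)) x_ij = 0

with h_i the leverages of W^{1/2} X (X'WX)^{-1} X' W^{1/2}. We solve them by
Newton iteration with step-halving, starting from β = 0.

Two closed forms anchor the implementation: with an intercept only and k
successes of n, the Firth estimate is π̂ = (k+½)/(n+1); on a saturated 2×2
table it equals the classic add-½-to-every-cell log odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.special import expit
from scipy.stats import norm

SEPARATION_NONE = "none"
SEPARATION_QUASI = "quasi"
SEPARATION_COMPLETE = "complete"

#: |standardized beta| beyond which monotone likelihood is suspected in
#: unpenalized fits (coefficient scale after dividing by column SD).
DIVERGENCE_BOUND = 15.0


@dataclass
class LogisticFit:
    """Result of a (penalized or standard) logistic fit.

    ``beta``, ``se``, ``p_wald`` are aligned with ``columns``. ``loglik`` is
    the (penalized, for Firth) log-likelihood at the estimate. Non-converged
    fits are returned with diagnostics in ``message``, never raised.
    """

    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_wald: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    penalized: bool
    separation_flag: str = "none"
    message: str = ""
    loglik_trace: list[float] = field(default_factory=list)

    def coef(self, column: str) -> float:
        return float(self.beta[self.columns.index(column)])

    def wald_summary(self, column: str, level: float = 0.95) -> dict:
        """Odds ratio with Wald CI and p-value for one term."""
        j = self.columns.index(column)
        zcrit = norm.ppf(0.5 + level / 2.0)
        b, s = float(self.beta[j]), float(self.se[j])
        return {
            "beta": b,
            "se": s,
            "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - zcrit * s)),
            "ci_high": float(np.exp(b + zcrit * s)),
            "p": float(self.p_wald[j]),
        }


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError(f"incompatible shapes X {X.shape}, y {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    return X, y


def _loglik(X, y, beta, penalized: bool) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if penalized:
        pi = expit(eta)
        w = pi * (1.0 - pi)
        sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        if sign <= 0:
            return -np.inf
        ll += 0.5 * logdet
    return ll


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Firth penalized log-likelihood l*(β) — exposed for oracle checks."""
    return _loglik(np.asarray(X, float), np.asarray(y, float), np.asarray(beta, float), True)


def _newton(X, y, penalized, tol, max_iter, max_halvings=5):
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(X, y, beta, penalized)
    trace = [ll]
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        xw = X * w[:, None]
        info = X.T @ xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            message = "singular Fisher information"
            break
        if penalized:
            h = np.einsum("ij,jk,ik->i", xw, info_inv, X)
            score = X.T @ (y - pi + h * (0.5 - pi))
        else:
            score = X.T @ (y - pi)
        step = info_inv @ score
        # step-halving: accept only non-decreasing (penalized) likelihood
        accepted = False
        for half in range(max_halvings + 1):
            candidate = beta + step / (2**half)
            ll_new = _loglik(X, y, candidate, penalized)
            if ll_new >= ll - 1e-12:
                beta, ll = candidate, ll_new
                accepted = True
                break
        trace.append(ll)
        if np.max(np.abs(score)) < tol and np.max(np.abs(step)) < tol:
            converged = True
            break
        if not accepted:
            message = "step-halving failed to improve the likelihood"
            break
    else:
        message = f"no convergence in {max_iter} iterations"
    return beta, ll, converged, it, message, trace


def _wald(X, beta, penalized_unused=None):
    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * norm.sf(np.abs(z))
    return se, p


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 25,
) -> LogisticFit:
    """Maximize the Firth penalized likelihood by Newton iteration.

    Standard errors come from the inverse Fisher information at the optimum;
    p-values are two-sided Wald. The fit starts at β = 0 and uses up to five
    step-halvings per iteration; convergence requires both the modified
    score and the step to fall below ``tol`` in max-norm. Non-convergence is
    reported in the returned fit, never raised.
    """
    X, y = _check_xy(X, y)
    cols = list(columns) if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    beta, ll, converged, n_iter, message, trace = _newton(X, y, True, tol, max_iter)
    try:
        se, p = _wald(X, beta)
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        converged, message = False, message or "singular information at optimum"
    return LogisticFit(
        columns=cols,
        beta=beta,
        se=se,
        p_wald=p,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        penalized=True,
        message=message,
        loglik_trace=trace,
    )


def fit_standard_logistic(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 25,
) -> LogisticFit:
    """Unpenalized logistic regression by the same Newton/IRLS machinery.

    On monotone likelihood the coefficients run off to infinity: if any
    standardized coefficient exceeds the divergence bound while the score
    has not vanished, the fit stops with ``converged=False`` and
    ``separation_flag='quasi'`` (separation suspected).
    """
    X, y = _check_xy(X, y)
    cols = list(columns) if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0

    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(X, y, beta, False)
    trace = [ll]
    converged, message, flag = False, "", SEPARATION_NONE
    it = 0
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - pi)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular Fisher information"
            break
        for half in range(6):
            candidate = beta + step / (2**half)
            ll_new = _loglik(X, y, candidate, False)
            if ll_new >= ll - 1e-12:
                beta, ll = candidate, ll_new
                break
        trace.append(ll)
        # On monotone likelihood the score decays as beta runs off to
        # infinity, but the Newton step stays O(1): judge "non-vanishing"
        # optimization by the step, not the raw score.
        diverged = np.max(np.abs(beta * sd)) > DIVERGENCE_BOUND
        still_moving = np.max(np.abs(step * sd)) > 1e-2
        if diverged and still_moving:
            message = "monotone likelihood: estimates diverging, separation suspected"
            flag = SEPARATION_QUASI
            break
        if np.max(np.abs(score)) < tol and np.max(np.abs(step)) < tol:
            converged = True
            break
    else:
        message = f"no convergence in {max_iter} iterations"
    try:
        se, p = _wald(X, beta)
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        p = np.full(k, np.nan)
    return LogisticFit(
        columns=cols,
        beta=beta,
        se=se,
        p_wald=p,
        loglik=ll,
        converged=converged,
        n_iter=it,
        penalized=False,
        separation_flag=flag,
        message=message,
        loglik_trace=trace,
    )


def detect_separation(X: np.ndarray, y: np.ndarray, tol: float = 1e-7) -> str:
    """Classify a design as 'none', 'quasi' or 'complete' separation.

    Solves the linear-programming feasibility problem: does a direction
    d ≠ 0 exist with d'x_i ≥ 0 for every case and d'x_i ≤ 0 for every
    control? If the best achievable total margin is zero the classes
    overlap ('none'); otherwise a second program checks whether every
    margin can be made strictly positive ('complete') or only some
    ('quasi').
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    signs = 2.0 * y - 1.0
    A = X * signs[:, None]  # want A d >= 0, ideally > 0
    n, k = A.shape
    # LP1: maximize sum(A d) subject to A d >= 0, -1 <= d <= 1
    res = linprog(
        c=-A.sum(axis=0),
        A_ub=-A,
        b_ub=np.zeros(n),
        bounds=[(-1.0, 1.0)] * k,
        method="highs",
    )
    if not res.success or -res.fun <= tol * max(n, 1):
        return SEPARATION_NONE
    # LP2: maximize t subject to A d >= t, t <= 1, -1 <= d <= 1
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A, np.ones((n, 1))])
    res2 = linprog(
        c=c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        bounds=[(-1.0, 1.0)] * k + [(None, 1.0)],
        method="highs",
    )
    if res2.success and -res2.fun > tol:
        return SEPARATION_COMPLETE
    return SEPARATION_QUASI
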