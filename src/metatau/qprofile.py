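"""Q-profile interval and the generalised Paule-Mandel estimator.

The pivot is the weighted residual sum of squares of the generalised
least-squares fit at a candidate tau^2,

    Q(tau^2) = sum_i (y_i - x_i beta_hat(tau^2))^2 / (sigma_i^2 + tau^2),
    beta_hat(tau^2) = (X' Sigma^{-1} X)^{-1} X' Sigma^{-1} y,

which follows a chi-square distribution with n - p degrees of freedom when
tau^2 is the true value. Its derivative has the remarkably simple closed form

    dQ/dtau^2 = - sum_i (y_i - x_i beta_hat)^2 / (sigma_i^2 + tau^2)^2 < 0,

because the indirect dependence through beta_hat vanishes at the weighted
least-squares optimum (an envelope argument). Monotonicity makes test
inversion yield an interval, and the derivative powers a Newton-Raphson
solver for Q(tau^2) = c. The Paule-Mandel estimate solves Q(tau^2) = n - p
(equivalently, it is the empirical Bayes estimator) and always lies inside
the same-level Q-profile interval under the [0, 0] convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import brentq
from scipy.stats import chi2

from .data import MetaRegressionDataset, RankError
from .genq import IntervalResult, _CONVENTIONS
from .quadform import CONVENTIONAL, build_B, moment_estimate

__all__ = [
    "PivotState",
    "q_profile",
    "q_profile_derivative",
    "newton_solve",
    "paule_mandel",
    "empirical_bayes",
    "qprofile_ci",
]

_Q_TOL = 1e-8
_TAU2_TOL = 1e-10
_MAX_ITER = 100
_BRACKET_CAP = 1e6


@dataclass
class PivotState:
    """Outcome of solving Q(tau^2) = c.

    ``no_positive_root`` flags the case Q(0) <= c, where the solution is
    truncated to tau^2 = 0. ``trajectory`` records the Newton iterates for
    diagnostics; ``used_bisection`` marks the safeguarded fallback.
    """

    tau2: float
    Q_value: float
    dQ: float
    target_c: float
    iterations: int
    converged: bool
    no_positive_root: bool = False
    used_bisection: bool = False
    trajectory: list = field(default_factory=list)


def _gls_fit(dataset: MetaRegressionDataset, tau2: float):
    """beta_hat(tau^2), residuals and total variances s_i = sigma_i^2 + tau^2."""
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    s = dataset.sigma2 + tau2
    w = 1.0 / s
    X = dataset.X
    Xw = w[:, None] * X
    M = X.T @ Xw
    try:
        c, low = linalg.cho_factor(M)
        beta = linalg.cho_solve((c, low), Xw.T @ dataset.y)
    except linalg.LinAlgError as exc:
        raise RankError(f"X' Sigma^{{-1}} X is singular at tau2={tau2:g}: {exc}") from exc
    resid = dataset.y - X @ beta
    return beta, resid, s


def q_profile(dataset: MetaRegressionDataset, tau2: float) -> tuple[float, np.ndarray]:
    """The pivot Q(tau^2) and the GLS coefficients beta_hat(tau^2)."""
    beta, resid, s = _gls_fit(dataset, tau2)
    return float(np.sum(resid * resid / s)), beta


def q_profile_derivative(dataset: MetaRegressionDataset, tau2: float) -> float:
    """dQ/dtau^2 = - sum residual_i^2 / (sigma_i^2 + tau^2)^2 (always <= 0)."""
    _, resid, s = _gls_fit(dataset, tau2)
    return float(-np.sum(resid * resid / (s * s)))


def _q_and_dq(dataset: MetaRegressionDataset, tau2: float) -> tuple[float, float]:
    _, resid, s = _gls_fit(dataset, tau2)
    r2 = resid * resid
    return float(np.sum(r2 / s)), float(-np.sum(r2 / (s * s)))


def newton_solve(
    dataset: MetaRegressionDataset,
    c: float,
    tau2_start: float | None = None,
    max_iter: int = _MAX_ITER,
) -> PivotState:
    """Solve Q(tau^2) = c by Newton-Raphson with zero-truncation.

    Update: tau_{k+1} = tau_k + (Q(tau_k) - c) / sum_i r_i^2/(s_i^2+tau_k)^2,
    replacing any negative iterate by zero. Starting value: the truncated
    moments estimate unless supplied. If Q(0) <= c no positive root exists and
    tau^2 = 0 is returned with ``no_positive_root`` set. A bisection fallback
    guards against the (rare) non-convergent trajectory; monotonicity and
    continuity of Q guarantee the fallback succeeds.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    q0, dq0 = _q_and_dq(dataset, 0.0)
    if q0 <= c:
        return PivotState(tau2=0.0, Q_value=q0, dQ=dq0, target_c=c, iterations=0,
                          converged=True, no_positive_root=True, trajectory=[0.0])
    if tau2_start is None:
        tau2_start = moment_estimate(build_B(dataset, CONVENTIONAL)).tau2
    t = max(0.0, float(tau2_start))
    traj = [t]
    for k in range(1, max_iter + 1):
        q, dq = _q_and_dq(dataset, t)
        if dq == 0.0:  # all residuals vanished; any tau^2 gives Q = 0 < c
            break
        t_new = t + (q - c) / (-dq)
        if t_new < 0.0:
            t_new = 0.0
        traj.append(t_new)
        q_new, dq_new = _q_and_dq(dataset, t_new)
        if abs(t_new - t) < _TAU2_TOL or abs(q_new - c) < _Q_TOL:
            return PivotState(tau2=t_new, Q_value=q_new, dQ=dq_new, target_c=c,
                              iterations=k, converged=True, trajectory=traj)
        t = t_new
    # safeguarded fallback: bisection on the monotone decreasing Q(t) - c
    f = lambda x: q_profile(dataset, x)[0] - c
    hi = max(t, 1.0)
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            return PivotState(tau2=t, Q_value=q, dQ=dq, target_c=c,
                              iterations=max_iter, converged=False, trajectory=traj)
    root = brentq(f, 0.0, hi, xtol=_TAU2_TOL)
    q_r, dq_r = _q_and_dq(dataset, root)
    return PivotState(tau2=float(root), Q_value=q_r, dQ=dq_r, target_c=c,
                      iterations=max_iter, converged=True, used_bisection=True,
                      trajectory=traj + [float(root)])


def paule_mandel(dataset: MetaRegressionDataset, tau2_start: float | None = None) -> float:
    """Generalised Paule-Mandel estimate: the tau^2 solving Q(tau^2) = n - p,
    or zero if Q(0) <= n - p. Unique by monotonicity of Q. Equivalent to the
    empirical Bayes estimator."""
    state = newton_solve(dataset, c=float(dataset.n - dataset.p), tau2_start=tau2_start)
    if not state.converged:
        raise RuntimeError("Paule-Mandel solver failed to converge")
    return state.tau2


#: The empirical Bayes estimator coincides with the Paule-Mandel estimator.
empirical_bayes = paule_mandel


def qprofile_ci(
    dataset: MetaRegressionDataset,
    level: float = 0.95,
    convention: str = "zero-zero",
) -> IntervalResult:
    """Q-profile (1 - alpha) confidence interval for tau^2.

    Three cases, with q_lo/q_hi the alpha/2 and 1 - alpha/2 chi-square(n-p)
    quantiles:

    (i)   Q(0) <  q_lo : no tau^2 accepted -> [0, 0] or empty set;
    (ii)  q_lo <= Q(0) <= q_hi : interval [0, U] with Q(U) = q_lo;
    (iii) Q(0) >  q_hi : interval [L, U] with Q(L) = q_hi, Q(U) = q_lo.

    Point estimate: the Paule-Mandel solution of Q(tau^2) = n - p, which is
    always contained in the interval under the zero-zero convention.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    alpha = 1.0 - level
    df = dataset.n - dataset.p
    q_lo = chi2.ppf(alpha / 2.0, df)
    q_hi = chi2.ppf(1.0 - alpha / 2.0, df)
    q0, _ = q_profile(dataset, 0.0)
    pm = paule_mandel(dataset)
    diag = {"Q_at_zero": q0, "chi2_lower": q_lo, "chi2_upper": q_hi}

    if q0 < q_lo:  # case (i): highly homogeneous data
        status = "empty-set" if convention == "empty" else "lower-at-zero"
        return IntervalResult(0.0, 0.0, level, status, convention, "qprofile", pm, diag)

    upper_state = newton_solve(dataset, c=q_lo, tau2_start=pm)
    if not upper_state.converged:
        raise RuntimeError(f"upper-bound solve failed (case diagnostics: {diag})")
    upper = upper_state.tau2
    diag["upper_iterations"] = upper_state.iterations

    if q0 <= q_hi:  # case (ii)
        return IntervalResult(0.0, float(upper), level, "lower-at-zero",
                              convention, "qprofile", pm, diag)

    lower_state = newton_solve(dataset, c=q_hi, tau2_start=pm)  # case (iii)
    if not lower_state.converged:
        raise RuntimeError(f"lower-bound solve failed (case diagnostics: {diag})")
    diag["lower_iterations"] = lower_state.iterations
    return IntervalResult(float(lower_state.tau2), float(upper), level,
                          "ordinary", convention, "qprofile", pm, diag)
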