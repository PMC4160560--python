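"""Confidence intervals for tau^2 by inverting the generalised Q test, and I^2.

A candidate value tau_0^2 lies in the (1 - alpha) confidence set when both

    P(Q_a >= q_a ; tau^2 = tau_0^2) >= alpha/2      (lower-tail condition)
    P(Q_a <= q_a ; tau^2 = tau_0^2) >= alpha/2      (upper-tail condition)

with q_a the observed statistic. Because the CDF of Q_a is decreasing in
tau^2 the accepted set is an interval. When even tau^2 = 0 fails the
upper-tail condition the data look "highly homogeneous": depending on the
chosen convention the result is the degenerate interval [0, 0] (which raises
coverage by alpha/2 at tau^2 = 0, hence is conservative) or an empty set
(which keeps the nominal coverage everywhere).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .data import MetaRegressionDataset
from .quadform import (
    CONVENTIONAL,
    QuadForm,
    WeightSpec,
    build_B,
    moment_estimate,
    qa_cdf,
)

__all__ = [
    "IntervalResult",
    "HeterogeneitySummary",
    "genq_statistic",
    "genq_ci",
    "i_squared",
    "i_squared_interval",
]

_CONVENTIONS = ("zero-zero", "empty")
_BRACKET_CAP = 1e6
_TAU2_XTOL = 1e-8


@dataclass(frozen=True)
class IntervalResult:
    """Two-sided interval for tau^2 (or a monotone transform of it).

    ``status`` is ``ordinary`` (both endpoints solve a tail equation),
    ``lower-at-zero`` (the lower-tail condition already holds at tau^2 = 0,
    so the lower bound is zero), or ``empty-set`` (no tau^2 accepted; only
    reported under the ``empty`` convention — the ``zero-zero`` convention
    maps that case to [0, 0]).
    """

    lower: float
    upper: float
    level: float
    status: str
    convention: str
    method: str
    point_estimate: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError("interval endpoints out of order")
        if self.status == "empty-set" and self.convention != "empty":
            raise ValueError("empty-set status requires the 'empty' convention")

    @property
    def is_empty(self) -> bool:
        return self.status == "empty-set"

    @property
    def is_degenerate(self) -> bool:
        return self.upper == 0.0

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        """Membership; the empty set contains nothing (unlike [0, 0])."""
        if self.is_empty:
            return False
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class HeterogeneitySummary:
    """tau^2 together with the 'typical' within-study variance sigma_t^2 and
    I^2 = tau^2 / (sigma_t^2 + tau^2)."""

    tau2: float
    sigma_t2: float
    I2: float


def genq_statistic(dataset: MetaRegressionDataset, weights: WeightSpec = CONVENTIONAL) -> float:
    """Observed generalised heterogeneity statistic Q_a = y'By."""
    return build_B(dataset, weights).statistic()


def _expand_upper_bracket(f, start: float) -> float:
    """Double an upper bracket until f flips sign (f(0) > 0 assumed)."""
    hi = max(start, 1e-4)
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            raise RuntimeError(
                f"no sign change for interval bound below tau^2 = {_BRACKET_CAP:g}; "
                f"last bracket upper end {hi / 2.0:g}"
            )
    return hi


def genq_ci(
    dataset: MetaRegressionDataset,
    weights: WeightSpec = CONVENTIONAL,
    level: float = 0.95,
    convention: str = "zero-zero",
) -> IntervalResult:
    """Equal-tailed (1 - level gives alpha) test-inversion interval for tau^2.

    The upper bound U solves P(Q_a <= q_a; U) = alpha/2 and the lower bound L
    solves P(Q_a >= q_a; L) = alpha/2, with L = 0 whenever the observed
    statistic is not extreme at tau^2 = 0. Point estimate: the truncated
    moments estimate under the same weights. Exact under the model provided
    the weights are fixed constants.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    alpha = 1.0 - level
    qf = build_B(dataset, weights)
    q_obs = qf.statistic()
    est = moment_estimate(qf, q_obs)
    method = f"genq({weights.kind})"
    diag = {"q_obs": q_obs, "tau2_untruncated": est.tau2_untruncated,
            "se_untruncated": est.se_untruncated}

    cdf0 = qa_cdf(qf, q_obs, 0.0)
    diag["cdf_at_zero"] = cdf0
    if cdf0 < alpha / 2.0:
        # even tau^2 = 0 is rejected from below: empty confidence set
        status = "empty-set" if convention == "empty" else "lower-at-zero"
        return IntervalResult(0.0, 0.0, level, status, convention, method,
                              est.tau2, diag)

    # upper bound: CDF decreasing in tau^2, solve F(q_obs; t) = alpha/2
    f_upper = lambda t: qa_cdf(qf, q_obs, t) - alpha / 2.0
    hi = _expand_upper_bracket(f_upper, 10.0 * est.tau2 + 1.0)
    upper = brentq(f_upper, 0.0, hi, xtol=_TAU2_XTOL)

    # lower bound: survival increasing in tau^2, solve S(q_obs; t) = alpha/2
    sf0 = 1.0 - cdf0
    if sf0 >= alpha / 2.0:
        lower = 0.0
        status = "lower-at-zero"
    else:
        f_lower = lambda t: (1.0 - qa_cdf(qf, q_obs, t)) - alpha / 2.0
        lower = brentq(f_lower, 0.0, upper, xtol=_TAU2_XTOL)
        status = "ordinary"
    return IntervalResult(float(lower), float(upper), level, status, convention,
                          method, est.tau2, diag)


def typical_within_study_variance(dataset: MetaRegressionDataset) -> float:
    """sigma_t^2 = (n - p) / tr(B) with conventional weights A = W."""
    qf = build_B(dataset, CONVENTIONAL)
    return (dataset.n - dataset.p) / qf.trace_B


def i_squared(dataset: MetaRegressionDataset, tau2: float) -> HeterogeneitySummary:
    """I^2 — the share of total variance due to residual heterogeneity,
    using the typical within-study variance sigma_t^2 = (n - p)/tr(B)."""
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    st2 = typical_within_study_variance(dataset)
    return HeterogeneitySummary(tau2=float(tau2), sigma_t2=st2,
                                I2=tau2 / (st2 + tau2))


def i_squared_interval(dataset: MetaRegressionDataset, tau2_interval: IntervalResult) -> IntervalResult:
    """Map a tau^2 interval to an I^2 interval endpoint-by-endpoint.

    Valid because I^2 is a strictly increasing function of tau^2.
    """
    st2 = typical_within_study_variance(dataset)
    g = lambda t: t / (st2 + t) if math.isfinite(t) else 1.0
    return IntervalResult(
        lower=g(tau2_interval.lower),
        upper=g(tau2_interval.upper),
        level=tau2_interval.level,
        status=tau2_interval.status,
        convention=tau2_interval.convention,
        method="i2-" + tau2_interval.method,
        point_estimate=g(tau2_interval.point_estimate),
        diagnostics={"sigma_t2": st2},
    )
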