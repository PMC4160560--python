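"""Quadratic-form machinery for generalised Cochran heterogeneity statistics.

The generalised heterogeneity statistic for a meta-regression with arbitrary
fixed positive weights a_i is

    Q_a = sum_i a_i (y_i - yhat_i)^2 = y' B y,
    B   = A - A X (X' A X)^{-1} X' A,          A = diag(a_i),

with yhat the fitted values of the A-weighted regression. Writing
Sigma = Delta + tau^2 I (Delta = diag(sigma_i^2)), under the random-effects
model Q_a is distributed as a weighted sum of n - p independent chi-square(1)
variables whose weights are the nonzero eigenvalues of
S = Sigma^{1/2} B Sigma^{1/2} — equivalently of (I - H) A Sigma, with H the
hat matrix of the A^{1/2} X regression. Those eigenvalues increase in tau^2,
so the CDF of Q_a decreases in tau^2, which is what makes test inversion
deliver genuine intervals.

This module builds B, evaluates the weighted chi-square distribution (Imhof's
characteristic-function inversion), supplies the exact mean/variance of Q_a,
and implements the moments (DerSimonian–Laird-type) estimator of tau^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, special

from .data import MetaRegressionDataset, RankError

__all__ = [
    "WeightSpec",
    "QuadForm",
    "EigenSpectrum",
    "MomentEstimate",
    "RandomWeightsWarning",
    "build_B",
    "eigen_spectrum",
    "qa_cdf",
    "qa_moments",
    "moment_estimate",
    "weighted_chisq_cdf",
]

_WEIGHT_KINDS = ("conventional", "inverse-sd", "total-variance", "custom")


class RandomWeightsWarning(UserWarning):
    """Weights depend on an estimated tau^2, so the exactness theory is only
    approximate (the weights are random, not fixed constants)."""


@dataclass(frozen=True)
class WeightSpec:
    """Choice of the fixed positive weights a_i defining Q_a.

    kind:
        ``conventional``   a_i = 1/sigma_i^2 (recovers the classical Q)
        ``inverse-sd``     a_i = 1/sigma_i (suited when some heterogeneity
                           is anticipated but its size is unknown)
        ``total-variance`` a_i = 1/(sigma_i^2 + tau2_hat); exactness theory
                           holds only approximately (weights are random)
        ``custom``         explicit positive vector in ``values``
    tau2:
        plug-in value for ``total-variance``; if None the truncated moments
        estimate under conventional weights is used.
    """

    kind: str = "conventional"
    values: np.ndarray | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _WEIGHT_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}; choose from {_WEIGHT_KINDS}")
        if self.kind == "custom":
            if self.values is None:
                raise ValueError("custom weights require an explicit vector")
            object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    def realize(self, dataset: MetaRegressionDataset) -> np.ndarray:
        """Concrete a_i vector for this dataset."""
        if self.kind == "conventional":
            a = 1.0 / dataset.sigma2
        elif self.kind == "inverse-sd":
            a = 1.0 / np.sqrt(dataset.sigma2)
        elif self.kind == "total-variance":
            t2 = self.tau2
            if t2 is None:
                qf = build_B(dataset, WeightSpec("conventional"))
                t2 = moment_estimate(qf).tau2
            warnings.warn(
                "total-variance weights use an estimated tau^2; the resulting "
                "interval is exact only approximately",
                RandomWeightsWarning,
                stacklevel=2,
            )
            a = 1.0 / (dataset.sigma2 + t2)
        else:
            a = self.values
            if a.shape[0] != dataset.n:
                raise ValueError("custom weights must have one entry per study")
        if np.any(a <= 0.0) or not np.all(np.isfinite(a)):
            raise ValueError("realized weights must be strictly positive and finite")
        return a


CONVENTIONAL = WeightSpec("conventional")
INVERSE_SD = WeightSpec("inverse-sd")


@dataclass
class QuadForm:
    """The matrix B of Q_a = y'By, together with its dataset and weights."""

    dataset: MetaRegressionDataset
    weights: WeightSpec
    a: np.ndarray
    B: np.ndarray

    @property
    def trace_B(self) -> float:
        return float(np.trace(self.B))

    @property
    def trace_B_Delta(self) -> float:
        """tr(B Delta) — the tau^2 = 0 expectation of Q_a."""
        return float(self.B.diagonal() @ self.dataset.sigma2)

    def statistic(self, y: np.ndarray | None = None) -> float:
        """Observed Q_a = y'By (defaults to the dataset's y)."""
        y = self.dataset.y if y is None else np.asarray(y, dtype=float)
        return float(y @ self.B @ y)


@dataclass(frozen=True)
class EigenSpectrum:
    """The n - p positive-part eigenvalues of S = Sigma^{1/2} B Sigma^{1/2},
    sorted non-increasing; the remaining p eigenvalues are structural zeros."""

    tau2: float
    lambdas: np.ndarray


def build_B(dataset: MetaRegressionDataset, weights: WeightSpec = CONVENTIONAL) -> QuadForm:
    """Construct B = A - A X (X'AX)^{-1} X'A for the given weights."""
    a = weights.realize(dataset)
    X = dataset.X
    AX = a[:, None] * X
    M = X.T @ AX
    try:
        c, low = linalg.cho_factor(M)
        Minv_XtA = linalg.cho_solve((c, low), AX.T)
    except linalg.LinAlgError as exc:
        raise RankError(f"X'AX is singular: {exc}") from exc
    B = np.diag(a) - AX @ Minv_XtA
    B = 0.5 * (B + B.T)
    return QuadForm(dataset=dataset, weights=weights, a=a, B=B)


def eigen_spectrum(qf: QuadForm, tau2: float, zero_rtol: float = 1e-10) -> EigenSpectrum:
    """Eigenvalues of S = Sigma^{1/2} B Sigma^{1/2} at the given tau^2.

    Exactly p of the n eigenvalues are zero; eigenvalues below
    ``zero_rtol * lambda_max`` are treated as those structural zeros and only
    the n - p positive-part values are returned (non-increasing order).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    s = qf.dataset.sigma2 + tau2
    r = np.sqrt(s)
    S = r[:, None] * qf.B * r[None, :]
    vals = np.linalg.eigvalsh(S)  # ascending
    n, p = qf.dataset.n, qf.dataset.p
    lam_max = vals[-1]
    tol = zero_rtol * max(lam_max, 0.0)
    n_small = int(np.sum(vals < tol))
    if n_small > p:
        raise RankError(
            f"{n_small} eigenvalues below tolerance but only p = {p} structural "
            "zeros expected; B appears rank deficient"
        )
    if np.any(vals[:p] >= tol):
        raise RankError(
            "expected the p smallest eigenvalues of S to vanish; got "
            f"{vals[:p]!r} against tolerance {tol:g}"
        )
    lambdas = np.clip(vals[p:], 0.0, None)[::-1].copy()
    return EigenSpectrum(tau2=float(tau2), lambdas=lambdas)


def weighted_chisq_cdf(lambdas, q: float, eps: float = 1e-8,
                       max_terms: int = 20_000) -> float:
    """P(sum_i lambda_i chi^2_{1,i} <= q) by a series of central chi-squares.

    Expands the distribution in central chi-square CDFs (Ruben's expansion,
    the series underlying Farebrother's algorithm): with beta = min_i
    lambda_i,

        P(Q <= q) = sum_{k>=0} a_k P(chi^2_{m+2k} <= q/beta),

    where a_0 = prod_i sqrt(beta/lambda_i) and, with
    c_k = sum_i (1 - beta/lambda_i)^k,

        a_k = (1/(2k)) sum_{j=0}^{k-1} c_{k-j} a_j.

    All a_k are non-negative and sum to one, so the truncation error after K
    terms is at most 1 - sum_{k<=K} a_k; the series is summed until that
    bound drops below ``eps``. Warns with the achieved bound if ``max_terms``
    is hit first.
    """
    lam = np.asarray(lambdas, dtype=float).ravel()
    lam = lam[lam > 0.0]
    if lam.size == 0:
        return 1.0 if q >= 0 else 0.0
    if q <= 0.0:
        return 0.0
    m = lam.size
    beta = lam.min()
    r = 1.0 - beta / lam  # all in [0, 1)
    if np.all(r == 0.0):  # equal weights: plain chi-square
        return float(special.gammainc(0.5 * m, 0.5 * q / beta))

    a = np.empty(max_terms)
    c = np.empty(max_terms)
    a[0] = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    partial = a[0]
    pow_r = np.ones(m)
    k_stop = max_terms - 1
    for k in range(1, max_terms):
        pow_r *= r
        c[k] = pow_r.sum()
        a[k] = 0.5 / k * float(np.dot(c[k:0:-1], a[:k]))
        partial += a[k]
        if 1.0 - partial < eps:
            k_stop = k
            break
    else:
        warnings.warn(
            "weighted chi-square CDF: series truncated at "
            f"{max_terms} terms; achieved error bound {1.0 - partial:.2e}",
            stacklevel=2,
        )
    ks = np.arange(k_stop + 1)
    cdfs = special.gammainc(0.5 * (m + 2 * ks), 0.5 * q / beta)
    return float(np.clip(np.dot(a[: k_stop + 1], cdfs), 0.0, 1.0))


def qa_cdf(qf: QuadForm, q: float, tau2: float) -> float:
    """CDF of Q_a at q under the model with the given tau^2.

    Decreasing in tau^2 for fixed q (the eigenvalues of S increase in tau^2),
    which is the monotonicity that test inversion relies on.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    spec = eigen_spectrum(qf, tau2)
    return weighted_chisq_cdf(spec.lambdas, q)


def qa_moments(qf: QuadForm, tau2: float) -> tuple[float, float]:
    """Exact mean and variance of Q_a at the given tau^2.

        E(Q_a)   = tr(B Delta) + tr(B) tau^2
        Var(Q_a) = 2 tr(B Sigma B Sigma)
                 = 2 tr(BDBD) + 4 tau^2 tr(BDB) + 2 tau^4 tr(B^2)
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    B = qf.B
    s2 = qf.dataset.sigma2
    mean = qf.trace_B_Delta + qf.trace_B * tau2
    B2 = B * B
    tr_BDBD = float(np.sum(B2 * np.outer(s2, s2)))
    tr_BDB = float(np.sum(B2 * s2[None, :]))
    tr_B2 = float(np.sum(B2))
    variance = 2.0 * tr_BDBD + 4.0 * tau2 * tr_BDB + 2.0 * tau2 * tau2 * tr_B2
    return mean, variance


@dataclass(frozen=True)
class MomentEstimate:
    """Moments-based tau^2 estimate from Q_a.

    ``tau2_untruncated`` is unbiased; ``tau2`` truncates it at zero (positive
    bias). ``se_untruncated`` is sqrt(Var(Q_a))/tr(B) with the truncated
    estimate plugged into Var(Q_a); it is descriptive only — no
    normal-approximation interval is built from it, because the distribution
    of Q_a is far too skewed at meta-analytic sample sizes.
    """

    tau2_untruncated: float
    tau2: float
    se_untruncated: float


def moment_estimate(qf: QuadForm, q_obs: float | None = None) -> MomentEstimate:
    """Method-of-moments estimate of tau^2 from the observed Q_a.

        tau2_u = (Q_a - tr(B Delta)) / tr(B)

    With conventional weights and an intercept-only design this is exactly the
    DerSimonian–Laird estimator.
    """
    tr_B = qf.trace_B
    if tr_B <= 0.0:
        raise ValueError("tr(B) must be positive")
    if q_obs is None:
        q_obs = qf.statistic()
    if q_obs < 0:
        raise ValueError("q_obs must be non-negative")
    untrunc = (q_obs - qf.trace_B_Delta) / tr_B
    trunc = max(0.0, untrunc)
    _, var_q = qa_moments(qf, trunc)
    se = float(np.sqrt(var_q)) / tr_B
    return MomentEstimate(tau2_untruncated=float(untrunc), tau2=float(trunc), se_untruncated=se)
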