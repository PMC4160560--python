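"""Model/Results interface for random-effects meta-regression.

`MetaRegression` holds the (y, X, sigma2) data; ``fit`` produces a
`MetaRegressionResults` carrying the tau^2 point estimate, its interval, the
GLS coefficient estimates at the fitted tau^2, and I^2; ``fit_bayes``
produces a `BayesianMetaRegressionResults` wrapping the MCMC posterior.

Example
-------
>>> import numpy as np
>>> from metatau import MetaRegression
>>> y = [0.2, 0.6, 1.1, 0.4, 1.5, 0.9]
>>> v = [0.10, 0.08, 0.22, 0.15, 0.30, 0.12]
>>> x = [0, 0, 1, 0, 1, 1]
>>> res = MetaRegression.from_arrays(y, v, covariates=x).fit(method="qprofile")
>>> print(res.summary())              # doctest: +SKIP
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorSummary, PriorSpec, sample_posterior
from .data import MetaRegressionDataset
from .genq import IntervalResult, genq_ci, i_squared, i_squared_interval
from .qprofile import paule_mandel, q_profile, qprofile_ci, _gls_fit
from .quadform import CONVENTIONAL, WeightSpec, build_B, moment_estimate

__all__ = ["MetaRegression", "MetaRegressionResults", "BayesianMetaRegressionResults"]

_FIT_METHODS = ("qprofile", "genq", "moment", "paule-mandel", "empirical-bayes")


class MetaRegression:
    """Random-effects meta-regression model y_i ~ N(x_i beta, sigma_i^2 + tau^2).

    Parameters
    ----------
    y, sigma2 : effect estimates and their (known) within-study variances.
    covariates : optional (n, k) covariate array; an intercept column is
        prepended unless ``intercept_free``.
    """

    def __init__(self, y, sigma2, covariates=None, intercept_free: bool = False,
                 study_labels=None, covariate_names=None):
        self.dataset = MetaRegressionDataset.from_arrays(
            y, sigma2, covariates=covariates, intercept_free=intercept_free,
            study_labels=study_labels, covariate_names=covariate_names,
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_arrays(cls, y, sigma2, covariates=None, **kw) -> "MetaRegression":
        return cls(y, sigma2, covariates=covariates, **kw)

    @classmethod
    def from_dataset(cls, dataset: MetaRegressionDataset) -> "MetaRegression":
        obj = cls.__new__(cls)
        obj.dataset = dataset
        return obj

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **columns) -> "MetaRegression":
        """Build from a data frame; keyword arguments are the column roles of
        :meth:`MetaRegressionDataset.from_dataframe` (yi, vi, covariates, or
        the four 2x2 count columns)."""
        return cls.from_dataset(MetaRegressionDataset.from_dataframe(df, **columns))

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        method: str = "qprofile",
        weights: WeightSpec = CONVENTIONAL,
        level: float = 0.95,
        convention: str = "zero-zero",
    ) -> "MetaRegressionResults":
        """Estimate tau^2 and an interval for it, plus GLS coefficients.

        method:
            ``qprofile``       Paule-Mandel point estimate + Q-profile CI
            ``genq``           moments point estimate + generalised-Q CI
                               (under ``weights``)
            ``paule-mandel`` / ``empirical-bayes``  alias of ``qprofile``
            ``moment``         moments point estimate and its descriptive
                               standard error only (no interval; the
                               sampling distribution is too skewed for a
                               normal approximation)
        """
        if method not in _FIT_METHODS:
            raise ValueError(f"method must be one of {_FIT_METHODS}")
        ds = self.dataset
        se_tau2 = None
        if method in ("qprofile", "paule-mandel", "empirical-bayes"):
            interval = qprofile_ci(ds, level=level, convention=convention)
            tau2 = interval.point_estimate
            label = "qprofile"
        elif method == "genq":
            interval = genq_ci(ds, weights, level=level, convention=convention)
            tau2 = interval.point_estimate
            se_tau2 = interval.diagnostics.get("se_untruncated")
            label = interval.method
        else:  # moment
            est = moment_estimate(build_B(ds, weights))
            interval = None
            tau2 = est.tau2
            se_tau2 = est.se_untruncated
            label = f"moment({weights.kind})"
        beta, resid, s = _gls_fit(ds, tau2)
        Xw = ds.X / s[:, None]
        cov_beta = np.linalg.inv(ds.X.T @ Xw)
        return MetaRegressionResults(
            model=self, method=label, tau2=float(tau2), se_tau2=se_tau2,
            interval=interval, beta=beta, cov_beta=cov_beta, level=level,
        )

    def fit_bayes(
        self,
        prior: PriorSpec | str,
        chains: int = 3,
        burn_in: int = 10_000,
        kept: int = 200_000,
        seed: int | None = None,
        **kw,
    ) -> "BayesianMetaRegressionResults":
        """Posterior for (beta, tau^2); see :func:`metatau.bayes.sample_posterior`."""
        if isinstance(prior, str):
            from .bayes import parse_prior

            prior = parse_prior(prior)
        summary, draws = sample_posterior(
            self.dataset, prior, chains=chains, burn_in=burn_in, kept=kept,
            seed=seed, **kw,
        )
        return BayesianMetaRegressionResults(model=self, prior=prior,
                                             posterior=summary, draws=draws)


@dataclass
class MetaRegressionResults:
    """Frequentist fit: tau^2 estimate, its interval, and GLS coefficients.

    ``beta`` and ``bse`` are the generalized-least-squares estimates and
    standard errors at the fitted tau^2 (the usual plug-in inference for the
    covariate effects).
    """

    model: MetaRegression
    method: str
    tau2: float
    se_tau2: float | None
    interval: IntervalResult | None
    beta: np.ndarray
    cov_beta: np.ndarray
    level: float

    @property
    def dataset(self) -> MetaRegressionDataset:
        return self.model.dataset

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def i2(self) -> float:
        return i_squared(self.dataset, self.tau2).I2

    @property
    def i2_interval(self) -> IntervalResult | None:
        if self.interval is None:
            return None
        return i_squared_interval(self.dataset, self.interval)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.bse},
            index=self.dataset.covariate_names,
        )

    def to_row(self) -> dict:
        """Flat record for TSV/JSON reporting."""
        row = {
            "method": self.method,
            "tau2": self.tau2,
            "se_tau2": self.se_tau2,
            "lower": self.interval.lower if self.interval else None,
            "upper": self.interval.upper if self.interval else None,
            "level": self.level,
            "status": self.interval.status if self.interval else None,
            "convention": self.interval.convention if self.interval else None,
            "I2": self.i2,
        }
        ii = self.i2_interval
        row["I2_lower"] = ii.lower if ii else None
        row["I2_upper"] = ii.upper if ii else None
        return row

    def summary(self) -> str:
        ds = self.dataset
        lines = [
            "Random-effects meta-regression",
            "=" * 46,
            f"studies (n):        {ds.n}",
            f"coefficients (p):   {ds.p}",
            f"method:             {self.method}",
            f"tau^2 estimate:     {self.tau2:.4f}"
            + (f"  (se {self.se_tau2:.4f})" if self.se_tau2 is not None else ""),
        ]
        if self.interval is not None:
            lines.append(
                f"{100 * self.level:.0f}% CI for tau^2:  "
                f"({self.interval.lower:.4f}, {self.interval.upper:.4f})"
                f"  [{self.interval.status}]"
            )
        hs = i_squared(ds, self.tau2)
        lines.append(f"I^2:                {100 * hs.I2:.1f}%  (sigma_t^2 = {hs.sigma_t2:.4f})")
        lines.append("-" * 46)
        lines.append(f"{'':<12}{'coef':>10}{'se':>10}")
        for name, b, s in zip(ds.covariate_names, self.beta, self.bse):
            lines.append(f"{name:<12}{b:>10.4f}{s:>10.4f}")
        return "\n".join(lines)


@dataclass
class BayesianMetaRegressionResults:
    """Bayesian fit: posterior summaries and raw draws."""

    model: MetaRegression
    prior: PriorSpec
    posterior: PosteriorSummary
    draws: dict

    @property
    def tau2_credible_interval(self) -> tuple[float, float]:
        return self.posterior.credible_interval("tau2")

    def to_row(self) -> dict:
        t = self.posterior.table.loc["tau2"]
        return {
            "method": f"bayes[{self.prior.label()}]",
            "tau2": float(t["median"]),
            "tau2_mean": float(t["mean"]),
            "lower": float(t["q2.5"]),
            "upper": float(t["q97.5"]),
            "level": 0.95,
            "status": "credible",
            "converged": self.posterior.converged,
            "max_rhat": float(self.posterior.table["rhat"].max()),
        }

    def summary(self) -> str:
        lines = [
            "Bayesian random-effects meta-regression",
            "=" * 54,
            f"prior on tau^2:  {self.prior.label()}",
            f"chains: {self.posterior.chains}, burn-in: {self.posterior.burn_in}, "
            f"kept: {self.posterior.kept}",
            f"converged: {self.posterior.converged} "
            f"(max R-hat {self.posterior.table['rhat'].max():.3f}, "
            f"acceptance {self.posterior.acceptance_rate:.2f})",
            "-" * 54,
            self.posterior.table.round(4).to_string(),
        ]
        return "\n".join(lines)
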