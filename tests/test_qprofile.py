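import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2

from metatau import (
    MetaRegressionDataset,
    newton_solve,
    paule_mandel,
    empirical_bayes,
    q_profile,
    q_profile_derivative,
    qprofile_ci,
)

from conftest import random_dataset


def exact_plane_dataset(n=8):
    x = np.linspace(-1, 1, n)
    X = np.column_stack([np.ones(n), x])
    y = X @ np.array([0.2, 0.7])
    return MetaRegressionDataset(y=y, X=X, sigma2=np.full(n, 0.1))


class TestPivot:
    def test_zero_residuals_give_zero_for_all_tau2(self):
        ds = exact_plane_dataset()
        for t in (0.0, 0.3, 5.0):
            assert q_profile(ds, t)[0] == pytest.approx(0.0, abs=1e-18)

    def test_decreasing_to_zero_for_large_tau2(self):
        ds = random_dataset(9, n=10, p=2)
        grid = [0.0, 0.1, 1.0, 100.0, 1e8 * ds.sigma2.max()]
        vals = [q_profile(ds, t)[0] for t in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6

    def test_matches_generalized_least_squares_oracle(self):
        """Q(tau^2) equals the residual sum from an independently solved
        normal-equations GLS fit."""
        ds = random_dataset(44, n=9, p=2)
        tau2 = 0.17
        s = ds.sigma2 + tau2
        Sinv = np.diag(1.0 / s)
        beta_o = np.linalg.solve(ds.X.T @ Sinv @ ds.X, ds.X.T @ Sinv @ ds.y)
        q_o = float((ds.y - ds.X @ beta_o) @ Sinv @ (ds.y - ds.X @ beta_o))
        q, beta = q_profile(ds, tau2)
        assert q == pytest.approx(q_o, rel=1e-12)
        assert np.allclose(beta, beta_o, rtol=1e-12)


class TestDerivative:
    def test_zero_at_zero_residuals(self):
        assert q_profile_derivative(exact_plane_dataset(), 0.2) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_finite_difference(self, seed):
        """The closed-form derivative agrees with a finite difference of the
        full pivot — confirming that the indirect dependence through the
        fitted coefficients vanishes (envelope property)."""
        ds = random_dataset(seed + 7, n=10, p=2)
        for tau2 in (0.05, 0.3, 1.0):
            h = 1e-6
            fd = (q_profile(ds, tau2 + h)[0] - q_profile(ds, tau2 - h)[0]) / (2 * h)
            d = q_profile_derivative(ds, tau2)
            assert d == pytest.approx(fd, rel=1e-4)
            assert d < 0.0

    def test_nonpositive_on_grid(self):
        for seed in range(6):
            ds = random_dataset(seed + 60, n=8, p=2)
            for t in np.linspace(0.0, 2.0, 9):
                assert q_profile_derivative(ds, t) <= 0.0


class TestNewtonSolve:
    def test_no_positive_root_flagged(self, homogeneous_ds):
        c = homogeneous_ds.n - homogeneous_ds.p
        state = newton_solve(homogeneous_ds, c=float(c))
        assert state.tau2 == 0.0
        assert state.no_positive_root
        assert state.converged

    @pytest.mark.parametrize("seed", range(5))
    def test_residual_equation_satisfied(self, seed):
        ds = random_dataset(seed + 200, n=12, p=2, tau2=0.3)
        c = 6.0
        if q_profile(ds, 0.0)[0] <= c:
            pytest.skip("homogeneous draw")
        state = newton_solve(ds, c=c)
        assert state.converged
        assert abs(state.Q_value - c) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bisection(self, seed):
        ds = random_dataset(seed + 300, n=12, p=2, tau2=0.4)
        c = float(ds.n - ds.p)
        if q_profile(ds, 0.0)[0] <= c:
            pytest.skip("homogeneous draw")
        state = newton_solve(ds, c=c)
        root = brentq(lambda t: q_profile(ds, t)[0] - c, 0.0, 1e4, xtol=1e-12)
        assert state.tau2 == pytest.approx(root, abs=1e-6)

    def test_bad_start_still_converges(self, example16):
        state = newton_solve(example16, c=14.0, tau2_start=50.0)
        assert state.converged
        assert abs(state.Q_value - 14.0) < 1e-8


class TestPauleMandel:
    def test_pivot_at_estimate_equals_df(self, example16):
        """For the 16-study, p=2 design the estimate solves Q(tau^2) = 14."""
        assert q_profile(example16, 0.0)[0] > 14.0
        pm = paule_mandel(example16)
        assert q_profile(example16, pm)[0] == pytest.approx(14.0, abs=1e-6)

    def test_zero_for_homogeneous_data(self, homogeneous_ds):
        assert paule_mandel(homogeneous_ds) == 0.0

    def test_empirical_bayes_alias(self, example16):
        assert empirical_bayes(example16) == paule_mandel(example16)

    @pytest.mark.parametrize("seed", range(20))
    def test_contained_in_qprofile_interval(self, seed):
        """Under the zero-zero convention the Paule-Mandel estimate always
        lies inside the same-level Q-profile interval."""
        ds = random_dataset(seed + 400, n=10, p=2,
                            tau2=float(np.random.default_rng(seed).uniform(0, 0.4)))
        ci = qprofile_ci(ds, convention="zero-zero")
        pm = paule_mandel(ds)
        assert ci.lower - 1e-12 <= pm <= ci.upper + 1e-12


class TestQProfileCI:
    def test_case_i_highly_homogeneous(self, homogeneous_ds):
        ci = qprofile_ci(homogeneous_ds, convention="zero-zero")
        assert (ci.lower, ci.upper) == (0.0, 0.0)
        ci2 = qprofile_ci(homogeneous_ds, convention="empty")
        assert ci2.is_empty

    def test_case_iii_endpoints_hit_chi2_quantiles(self, example16):
        ci = qprofile_ci(example16, level=0.95)
        df = example16.n - example16.p
        assert ci.status == "ordinary"
        assert q_profile(example16, ci.lower)[0] == pytest.approx(
            chi2.ppf(0.975, df), abs=1e-6)
        assert q_profile(example16, ci.upper)[0] == pytest.approx(
            chi2.ppf(0.025, df), abs=1e-6)

    def test_case_ii_lower_at_zero(self):
        ds = random_dataset(123, n=12, p=2, tau2=0.0)
        q0 = q_profile(ds, 0.0)[0]
        df = ds.n - ds.p
        assert chi2.ppf(0.025, df) <= q0 <= chi2.ppf(0.975, df)
        ci = qprofile_ci(ds)
        assert ci.lower == 0.0 and ci.status == "lower-at-zero"
        assert q_profile(ds, ci.upper)[0] == pytest.approx(chi2.ppf(0.025, df), abs=1e-6)

    def test_intercept_only_matches_meta_analysis_oracle(self):
        """With no covariates the interval must agree with an independently
        coded meta-analysis Q-profile (bisection on the scalar pivot)."""
        rng = np.random.default_rng(88)
        n = 14
        sigma2 = rng.uniform(0.05, 0.4, n)
        y = 0.4 + np.sqrt(sigma2 + 0.2) * rng.standard_normal(n)
        ds = MetaRegressionDataset(y=y, X=np.ones((n, 1)), sigma2=sigma2)

        def q_scalar(t):
            w = 1.0 / (sigma2 + t)
            mu = np.sum(w * y) / w.sum()
            return float(np.sum(w * (y - mu) ** 2))

        lo_q, hi_q = chi2.ppf([0.025, 0.975], n - 1)
        assert q_scalar(0.0) > hi_q
        lower_o = brentq(lambda t: q_scalar(t) - hi_q, 0.0, 1e3, xtol=1e-10)
        upper_o = brentq(lambda t: q_scalar(t) - lo_q, 0.0, 1e3, xtol=1e-10)
        ci = qprofile_ci(ds)
        assert ci.lower == pytest.approx(lower_o, abs=1e-6)
        assert ci.upper == pytest.approx(upper_o, abs=1e-6)


class TestAgainstMetafor:
    def test_small_fixture_matches_metafor(self, tmp_path, example16):
        """Cross-check the Paule-Mandel estimate and Q-profile interval
        against the metafor R package (empirical-Bayes fit + profile CI) on
        one dataset."""
        csv = tmp_path / "fix.csv"
        example16.to_csv(csv)
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            fit <- rma(yi=d$yi, vi=d$vi, mods=~d$x1, method="EB")
            ci <- confint(fit)
            cat(sprintf("%.10f %.10f %.10f\\n", fit$tau2,
                        ci$random["tau^2","ci.lb"], ci$random["tau^2","ci.ub"]))
            fitg <- rma(yi=d$yi, vi=d$vi, mods=~d$x1, method="GENQ", weights=1/d$vi)
            cat(sprintf("%.10f\\n", fitg$tau2))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = out.stdout.strip().splitlines()
        pm_r, lo_r, hi_r = map(float, lines[0].split())
        genq_r = float(lines[1])
        assert paule_mandel(example16) == pytest.approx(pm_r, abs=2e-5)
        ci = qprofile_ci(example16)
        assert ci.lower == pytest.approx(lo_r, abs=2e-5)
        assert ci.upper == pytest.approx(hi_r, abs=2e-5)
        from metatau import CONVENTIONAL, build_B, moment_estimate

        assert moment_estimate(build_B(example16, CONVENTIONAL)).tau2 == pytest.approx(
            genq_r, abs=1e-7)
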