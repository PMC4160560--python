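import numpy as np
import pytest
from scipy.stats import chi2

from metatau import (
    CONVENTIONAL,
    INVERSE_SD,
    MetaRegressionDataset,
    WeightSpec,
    build_B,
    eigen_spectrum,
    moment_estimate,
    qa_cdf,
    qa_moments,
    weighted_chisq_cdf,
)
from metatau.quadform import RandomWeightsWarning

from conftest import random_dataset


class TestBuildB:
    def test_two_study_intercept_only_unit_weights(self):
        ds = MetaRegressionDataset(y=[0.1, 0.5], X=np.ones((2, 1)), sigma2=[0.2, 0.3])
        qf = build_B(ds, WeightSpec("custom", values=[1.0, 1.0]))
        assert np.allclose(qf.B, [[0.5, -0.5], [-0.5, 0.5]])
        assert qf.trace_B == pytest.approx(1.0)

    @pytest.mark.parametrize("weights", [CONVENTIONAL, INVERSE_SD])
    @pytest.mark.parametrize("seed", range(5))
    def test_B_annihilates_X(self, weights, seed):
        ds = random_dataset(seed, n=9, p=2)
        qf = build_B(ds, weights)
        assert np.max(np.abs(qf.B @ ds.X)) < 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_B_symmetric_psd(self, seed):
        qf = build_B(random_dataset(seed, n=10, p=2))
        assert np.allclose(qf.B, qf.B.T)
        assert np.linalg.eigvalsh(qf.B).min() > -1e-10

    def test_statistic_matches_weighted_least_squares_rss(self):
        """y'By equals the weighted residual sum of squares from an explicit
        WLS fit with the same weights (the defining identity of Q_a)."""
        ds = random_dataset(123, n=6, p=2)
        qf = build_B(ds, CONVENTIONAL)
        w = 1.0 / ds.sigma2
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(sw[:, None] * ds.X, sw * ds.y, rcond=None)
        rss = float(np.sum(w * (ds.y - ds.X @ beta) ** 2))
        assert qf.statistic() == pytest.approx(rss, rel=1e-10)

    def test_total_variance_weights_warn(self):
        ds = random_dataset(5, n=10, p=2)
        with pytest.warns(RandomWeightsWarning):
            build_B(ds, WeightSpec("total-variance"))


class TestEigenSpectrum:
    def test_conventional_weights_null_spectrum_is_all_ones(self):
        """With A = W and tau^2 = 0, Q follows chi-square(n-p): all retained
        eigenvalues are 1."""
        ds = random_dataset(2, n=12, p=2)
        spec = eigen_spectrum(build_B(ds, CONVENTIONAL), 0.0)
        assert spec.lambdas.shape == (10,)
        assert np.allclose(spec.lambdas, 1.0, atol=1e-10)

    @pytest.mark.parametrize("weights", [CONVENTIONAL, INVERSE_SD])
    @pytest.mark.parametrize("tau2", [0.0, 0.1, 0.7])
    def test_matches_nonsymmetric_product_oracle(self, weights, tau2):
        """Spectrum equals the eigenvalues of (I - H) A Sigma, computed with
        a general (non-symmetric) eigensolver."""
        ds = random_dataset(31, n=9, p=2)
        qf = build_B(ds, weights)
        a = qf.a
        sa = np.sqrt(a)
        Xs = sa[:, None] * ds.X
        H = Xs @ np.linalg.solve(Xs.T @ Xs, Xs.T)
        ASigma = np.diag(a * (ds.sigma2 + tau2))
        oracle = np.sort(np.real(np.linalg.eigvals((np.eye(ds.n) - H) @ ASigma)))[::-1]
        spec = eigen_spectrum(qf, tau2)
        assert np.allclose(spec.lambdas, oracle[: ds.n - ds.p], atol=1e-9)
        assert np.allclose(oracle[ds.n - ds.p:], 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_elementwise_monotone_in_tau2(self, seed):
        ds = random_dataset(seed + 100, n=10, p=2)
        qf = build_B(ds, INVERSE_SD)
        lams = [eigen_spectrum(qf, t).lambdas for t in (0.0, 0.1, 0.5, 2.0)]
        for lo, hi in zip(lams, lams[1:]):
            assert np.all(hi >= lo - 1e-12)


class TestWeightedChisqCDF:
    def test_reduces_to_chisq14(self):
        for q in (3.0, 10.0, 14.0, 25.0):
            assert weighted_chisq_cdf(np.ones(14), q) == pytest.approx(
                chi2.cdf(q, 14), abs=1e-7)

    def test_single_scaled_component(self):
        for q in (0.5, 2.0, 8.0):
            assert weighted_chisq_cdf([2.0], q) == pytest.approx(
                chi2.cdf(q / 2.0, 1), abs=1e-7)

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(99)
        lam = rng.uniform(0.2, 3.0, size=8)
        draws = (rng.standard_normal((200_000, 8)) ** 2 * lam).sum(axis=1)
        for q in np.quantile(draws, [0.1, 0.5, 0.9]):
            emp = np.mean(draws <= q)
            se = np.sqrt(emp * (1 - emp) / draws.size)
            assert abs(weighted_chisq_cdf(lam, q) - emp) < 3 * se

    def test_cdf_decreasing_in_tau2(self):
        ds = random_dataset(8, n=10, p=2)
        qf = build_B(ds, CONVENTIONAL)
        q = qf.statistic()
        vals = [qa_cdf(qf, q, t) for t in (0.0, 0.05, 0.2, 1.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMoments:
    def test_null_mean_is_degrees_of_freedom(self):
        ds = random_dataset(4, n=11, p=2)
        mean, _ = qa_moments(build_B(ds, CONVENTIONAL), 0.0)
        assert mean == pytest.approx(ds.n - ds.p, rel=1e-10)

    @pytest.mark.parametrize("tau2", [0.0, 0.2])
    def test_match_spectral_sums(self, tau2):
        """E(Q_a) = sum lambda_i and Var(Q_a) = 2 sum lambda_i^2."""
        ds = random_dataset(17, n=9, p=2)
        qf = build_B(ds, INVERSE_SD)
        lam = eigen_spectrum(qf, tau2).lambdas
        mean, var = qa_moments(qf, tau2)
        assert mean == pytest.approx(lam.sum(), rel=1e-9)
        assert var == pytest.approx(2.0 * np.sum(lam**2), rel=1e-9)

    def test_match_simulated_moments(self):
        ds = random_dataset(23, n=10, p=2)
        qf = build_B(ds, INVERSE_SD)
        tau2 = 0.2
        mean, var = qa_moments(qf, tau2)
        rng = np.random.default_rng(555)
        sd = np.sqrt(ds.sigma2 + tau2)
        Z = rng.standard_normal((100_000, ds.n)) * sd  # location cancels in Q_a
        q_draws = np.einsum("ri,ij,rj->r", Z, qf.B, Z)
        assert abs(q_draws.mean() - mean) < 4 * q_draws.std() / np.sqrt(q_draws.size)
        # SE of the sample variance from the empirical fourth central moment
        m4 = np.mean((q_draws - q_draws.mean()) ** 4)
        s2 = q_draws.var(ddof=1)
        var_se = np.sqrt((m4 - s2**2) / q_draws.size)
        assert abs(s2 - var) < 4 * var_se


class TestMomentEstimate:
    def test_zero_when_q_equals_null_mean(self):
        ds = random_dataset(3, n=10, p=2)
        qf = build_B(ds, CONVENTIONAL)
        est = moment_estimate(qf, q_obs=qf.trace_B_Delta)
        assert est.tau2_untruncated == pytest.approx(0.0, abs=1e-12)

    def test_equals_dersimonian_laird_intercept_only(self):
        """With conventional weights and no covariates the truncated moments
        estimate is the textbook DerSimonian-Laird formula."""
        rng = np.random.default_rng(77)
        n = 14
        sigma2 = rng.uniform(0.05, 0.5, n)
        y = 0.3 + np.sqrt(sigma2 + 0.15) * rng.standard_normal(n)
        ds = MetaRegressionDataset(y=y, X=np.ones((n, 1)), sigma2=sigma2)
        w = 1.0 / sigma2
        mu = np.sum(w * y) / w.sum()
        Q = np.sum(w * (y - mu) ** 2)
        dl = max(0.0, (Q - (n - 1)) / (w.sum() - np.sum(w**2) / w.sum()))
        est = moment_estimate(build_B(ds, CONVENTIONAL))
        assert est.tau2 == pytest.approx(dl, rel=1e-10)

    def test_untruncated_estimator_unbiased(self):
        """Mean of the untruncated estimate over 20,000 simulated datasets
        recovers the true tau^2 within Monte-Carlo error."""
        rng = np.random.default_rng(2024)
        n, tau2 = 20, 0.1
        sigma2 = rng.uniform(0.05, 0.4, n)
        x = rng.uniform(-1, 1, n)
        X = np.column_stack([np.ones(n), x])
        ds = MetaRegressionDataset(y=np.zeros(n), X=X, sigma2=sigma2)
        qf = build_B(ds, CONVENTIONAL)
        sd = np.sqrt(sigma2 + tau2)
        Z = rng.standard_normal((20_000, n)) * sd
        q_draws = np.einsum("ri,ij,rj->r", Z, qf.B, Z)
        ests = (q_draws - qf.trace_B_Delta) / qf.trace_B
        mc_se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - tau2) < 3 * mc_se

    def test_se_positive(self):
        est = moment_estimate(build_B(random_dataset(1, n=10, p=2)))
        assert est.se_untruncated > 0
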