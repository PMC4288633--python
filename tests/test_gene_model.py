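import numpy as np
import pytest
from scipy.special import logsumexp

from tempodose.gene_model import (
    GenePriors,
    estimate_dispersion,
    fit_gaussian,
    fit_negbin,
    fit_spike_slab,
    hat_trace,
    moderate_dispersions,
)
from tempodose.spline_basis import build_basis, place_knots


def dense_gaussian_posterior(y, W, prior_vars, s2e):
    """Independent closed-form conjugate oracle via the N x N covariance."""
    N = y.size
    pv = np.asarray(prior_vars, dtype=float)
    C = s2e * np.eye(N) + (W * pv) @ W.T
    Ci = np.linalg.inv(C)
    _, logdet = np.linalg.slogdet(C)
    logev = -0.5 * (N * np.log(2 * np.pi) + logdet + y @ Ci @ y)
    mean = (pv[:, None] * W.T) @ Ci @ y
    cov = np.diag(pv) - (pv[:, None] * W.T) @ Ci @ (W * pv)
    return logev, mean, cov


class TestGaussianExactness:
    def test_posterior_matches_dense_oracle(self, design_2x6, rng):
        """Grid-node posterior equals dense conjugate algebra to 1e-8."""
        d = design_2x6
        for _ in range(20):
            y = rng.standard_normal(d["N"])
            cn = rng.standard_normal(d["N"])
            s2g, s2e = np.exp(rng.uniform(-2, 1, size=2))
            tau2 = np.exp(rng.uniform(-1, 1))
            pi0 = rng.uniform(0.1, 0.9)
            pri = GenePriors(alpha_var=50.0, beta_pi0=pi0, beta_tau2=tau2)
            fit = fit_gaussian(y, d["X"], cn=cn, basis=d["basis"], priors=pri,
                               variances=(s2g, s2e))
            W = np.hstack([d["X"], cn[:, None], d["basis"].design])
            pv1 = np.r_[[50.0] * d["n"], tau2, [s2g] * 2]
            le1, m1, c1 = dense_gaussian_posterior(y, W, pv1, s2e)
            W0 = np.delete(W, d["n"], axis=1)
            pv0 = np.r_[[50.0] * d["n"], [s2g] * 2]
            le0, m0, c0 = dense_gaussian_posterior(y, W0, pv0, s2e)
            logml = np.logaddexp(np.log(pi0) + le0, np.log1p(-pi0) + le1)
            incl = np.exp(np.log1p(-pi0) + le1 - logml)
            assert abs(fit.log_marglik - logml) < 1e-8
            assert abs(fit.beta_inclusion - incl) < 1e-8
            assert abs(fit.beta_mean - incl * m1[d["n"]]) < 1e-8
            alpha_mix = incl * m1[: d["n"]] + (1 - incl) * m0[: d["n"]]
            np.testing.assert_allclose(fit.alpha_mean, alpha_mix, atol=1e-8)

    def test_flat_prior_limit_recovers_sample_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        X = np.ones((4, 1))
        fit = fit_gaussian(y, X, priors=GenePriors(alpha_var=1e10, beta_pi0=1.0),
                           variances=(1.0, 1.0))
        assert abs(fit.alpha_mean[0] - y.mean()) < 1e-6

    def test_generalized_ridge_solution(self, design_2x6, rng):
        """Posterior mean equals (X'X/s2e + P0)^-1 X'y/s2e at fixed variances."""
        d = design_2x6
        y = rng.standard_normal(d["N"])
        cn = rng.standard_normal(d["N"])
        pri = GenePriors(alpha_var=25.0, beta_pi0=1e-14, beta_tau2=0.5)
        fit = fit_gaussian(y, d["X"], cn=cn, basis=d["basis"], priors=pri,
                           variances=(0.4, 0.2))
        W = np.hstack([d["X"], cn[:, None], d["basis"].design])
        P0 = np.diag(1.0 / np.r_[[25.0] * 2, 0.5, [0.4] * 2])
        ridge = np.linalg.solve(W.T @ W / 0.2 + P0, W.T @ y / 0.2)
        np.testing.assert_allclose(
            np.r_[fit.alpha_mean, fit.beta_mean, fit.gamma_mean], ridge, atol=1e-8)

    def test_evidence_matches_brute_force_quadrature(self):
        """3-observation toy: closed-form evidence vs dense numerical
        integration of likelihood x prior over the latent parameter."""
        y = np.array([0.3, -0.1, 0.8])
        X = np.ones((3, 1))
        av, s2e = 2.0, 0.5
        fit = fit_gaussian(y, X, priors=GenePriors(alpha_var=av, beta_pi0=1.0),
                           variances=(1.0, s2e))
        grid = np.linspace(-8, 8, 20001)
        da = grid[1] - grid[0]
        ll = -0.5 * np.sum((y[None, :] - grid[:, None]) ** 2, axis=1) / s2e \
            - 1.5 * np.log(2 * np.pi * s2e)
        lp = -0.5 * grid**2 / av - 0.5 * np.log(2 * np.pi * av)
        oracle = logsumexp(ll + lp) + np.log(da)
        assert abs(fit.log_marglik - oracle) < 1e-6

    def test_zero_variance_response_flagged(self, design_2x6):
        fit = fit_gaussian(np.ones(12), design_2x6["X"], basis=design_2x6["basis"],
                           priors=GenePriors(beta_pi0=1.0), variances=(1.0, 1.0))
        assert "degenerate_y" in fit.flags

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="N >= q"):
            fit_gaussian(np.array([1.0]), np.ones((1, 2)), priors=GenePriors())


class TestSpikeSlab:
    def test_pure_spike_gives_zero_beta(self, design_2x6, rng):
        y = rng.standard_normal(12)
        cn = rng.standard_normal(12)
        fit = fit_spike_slab(y, design_2x6["X"], cn, design_2x6["basis"],
                             GenePriors(beta_pi0=1.0), variances=(1.0, 1.0))
        assert fit.beta_mean == 0.0 and fit.beta_inclusion == 0.0

    def test_flat_slab_limit_approaches_least_squares(self, design_2x6, rng):
        d = design_2x6
        cn = rng.standard_normal(12)
        y = 2.0 * cn + rng.normal(0, 0.1, 12)
        fit = fit_spike_slab(y, d["X"], cn, None,
                             GenePriors(beta_pi0=1e-14, beta_tau2=1e6, alpha_var=1e6),
                             variances=(1.0, 0.01))
        W = np.hstack([d["X"], cn[:, None]])
        beta_ls = np.linalg.lstsq(W, y, rcond=None)[0][-1]
        assert abs(fit.beta_mean - beta_ls) < 1e-4

    def test_inclusion_matches_quadrature_bayes_factor(self):
        """3-point toy with fixed variances: inclusion vs dense quadrature."""
        y = np.array([0.5, 1.1, -0.2])
        X = np.ones((3, 1))
        cn = np.array([1.0, 2.0, -1.0])
        av, tau2, s2e, pi0 = 3.0, 1.5, 0.4, 0.6
        fit = fit_spike_slab(y, X, cn, None,
                             GenePriors(alpha_var=av, beta_pi0=pi0, beta_tau2=tau2),
                             variances=(1.0, s2e))
        a = np.linspace(-8, 8, 1201)
        b = np.linspace(-8, 8, 1201)
        A, B = np.meshgrid(a, b, indexing="ij")
        da = (a[1] - a[0]) * (b[1] - b[0])
        resid2 = sum((y[i] - A - B * cn[i]) ** 2 for i in range(3))
        ll = -0.5 * resid2 / s2e - 1.5 * np.log(2 * np.pi * s2e)
        lpa = -0.5 * A**2 / av - 0.5 * np.log(2 * np.pi * av)
        lpb = -0.5 * B**2 / tau2 - 0.5 * np.log(2 * np.pi * tau2)
        log_e1 = logsumexp(ll + lpa + lpb) + np.log(da)
        resid2_0 = sum((y[i] - a) ** 2 for i in range(3))
        ll0 = -0.5 * resid2_0 / s2e - 1.5 * np.log(2 * np.pi * s2e)
        log_e0 = logsumexp(ll0 - 0.5 * a**2 / av - 0.5 * np.log(2 * np.pi * av)) \
            + np.log(a[1] - a[0])
        incl_oracle = np.exp(np.log1p(-pi0) + log_e1 - np.logaddexp(
            np.log(pi0) + log_e0, np.log1p(-pi0) + log_e1))
        assert abs(fit.beta_inclusion - incl_oracle) < 1e-3

    def test_constant_cn_flagged(self, design_2x6, rng):
        fit = fit_gaussian(rng.standard_normal(12), design_2x6["X"],
                           cn=np.ones(12), basis=design_2x6["basis"],
                           priors=GenePriors(), variances=(1.0, 1.0))
        assert "degenerate_cn" in fit.flags
        assert fit.beta_mean == 0.0 and np.isnan(fit.beta_inclusion)

    def test_shrinkage_monotone_in_pi0_and_tau2(self, design_2x6, rng):
        d = design_2x6
        cn = rng.standard_normal(12)
        y = 1.0 * cn + rng.normal(0, 0.3, 12)
        betas_pi0 = [
            abs(fit_gaussian(y, d["X"], cn=cn, basis=None,
                             priors=GenePriors(beta_pi0=p, beta_tau2=1.0),
                             variances=(1.0, 0.1)).beta_mean)
            for p in (0.05, 0.3, 0.6, 0.9, 0.99)
        ]
        assert np.all(np.diff(betas_pi0) <= 1e-12)
        betas_tau2 = [
            abs(fit_gaussian(y, d["X"], cn=cn, basis=None,
                             priors=GenePriors(beta_pi0=0.5, beta_tau2=t),
                             variances=(1.0, 0.1)).beta_mean)
            for t in (0.01, 0.1, 1.0, 10.0)
        ]
        assert np.all(np.diff(betas_tau2) >= -1e-12)

    def test_grid_evidence_converges_to_quadrature(self):
        """Marginal likelihood stabilizes as the hyperparameter grid refines."""
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.7, 12)
        X = np.ones((12, 1))
        times = np.tile(np.arange(1.0, 7.0), 2)
        basis = build_basis(times, place_knots(times, 2))
        pri = GenePriors(alpha_var=10.0, beta_pi0=1.0,
                         gamma_prec_shape=2.0, gamma_prec_rate=2.0,
                         eps_prec_shape=2.0, eps_prec_rate=2.0)
        ml = [fit_gaussian(y, X, basis=basis, priors=pri, grid_size=g).log_marglik
              for g in (5, 15, 25)]
        assert abs(ml[1] - ml[2]) < abs(ml[0] - ml[2]) + 1e-6
        assert abs(ml[1] - ml[2]) < 0.05


class TestHatTrace:
    def test_flat_prior_ols_trace_equals_q(self, design_2x6, rng):
        d = design_2x6
        y = rng.standard_normal(12)
        fit = fit_gaussian(y, d["X"], priors=GenePriors(alpha_var=1e8, beta_pi0=1.0),
                           variances=(1.0, 1.0))
        assert abs(hat_trace(fit, "all") - d["n"]) < 1e-4

    def test_trace_matches_dense_smoother(self, design_2x6, rng):
        d = design_2x6
        y = rng.standard_normal(12)
        cn = rng.standard_normal(12)
        s2g, s2e = 0.6, 0.3
        pri = GenePriors(alpha_var=20.0, beta_pi0=1e-14, beta_tau2=0.8)
        fit = fit_gaussian(y, d["X"], cn=cn, basis=d["basis"], priors=pri,
                           variances=(s2g, s2e))
        W = np.hstack([d["X"], cn[:, None], d["basis"].design])
        pv = np.r_[[20.0] * 2, 0.8, [s2g] * 2]
        H = (W * pv) @ W.T @ np.linalg.inv(s2e * np.eye(12) + (W * pv) @ W.T)
        assert abs(hat_trace(fit, "all") - np.trace(H)) < 1e-8
        Wf = W[:, :3]
        pvf = pv[:3]
        Hf = (Wf * pvf) @ Wf.T @ np.linalg.inv(s2e * np.eye(12) + (Wf * pvf) @ Wf.T)
        assert abs(hat_trace(fit, "spline") - (np.trace(H) - np.trace(Hf))) < 1e-8

    def test_spline_df_bounded_by_K(self, design_4x8, rng):
        d = design_4x8
        y = rng.standard_normal(32)
        fit = fit_gaussian(y, d["X"], basis=d["basis"],
                           priors=GenePriors(beta_pi0=1.0), grid_size=5)
        df = hat_trace(fit, "spline")
        assert 0.0 <= df <= 2.0 + 1e-9


class TestNegativeBinomial:
    def test_non_integer_counts_rejected(self, design_2x6):
        with pytest.raises(ValueError, match="integer"):
            fit_negbin(np.full(12, 0.5), design_2x6["X"], priors=GenePriors())

    def test_poisson_limit_matches_poisson_laplace_oracle(self, design_2x6, rng):
        d = design_2x6
        cn = rng.standard_normal(12)
        mu = np.exp(3.0 + 0.8 * cn)
        y = rng.poisson(mu).astype(float)
        pri = GenePriors(alpha_var=100.0, beta_pi0=1e-14, beta_tau2=4.0)
        fit = fit_negbin(y, d["X"], cn=cn, basis=None, priors=pri, dispersion=1e6)
        # independent oracle: Poisson Laplace via plain Newton
        W = np.hstack([d["X"], cn[:, None]])
        pv = np.array([100.0, 100.0, 4.0])
        u = np.zeros(3)
        for _ in range(200):
            eta = np.clip(W @ u, -30, 30)
            m = np.exp(eta)
            step = np.linalg.solve(W.T @ (W * m[:, None]) + np.diag(1 / pv),
                                   W.T @ (y - m) - u / pv)
            u += step
            if np.abs(step).max() < 1e-13:
                break
        assert abs(fit.beta_mean - u[2]) < 1e-3
        np.testing.assert_allclose(fit.alpha_mean, u[:2], atol=1e-3)

    def test_all_zero_counts_flagged_degenerate(self, design_2x6):
        fit = fit_negbin(np.zeros(12), design_2x6["X"], priors=GenePriors(beta_pi0=1.0),
                         dispersion=2.0)
        assert "degenerate_y" in fit.flags

    def test_zero_inflation_increases_evidence_for_zero_rich_counts(self, design_2x6, rng):
        d = design_2x6
        mu = np.exp(2.0)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu), 12).astype(float)
        y[rng.random(12) < 0.5] = 0.0  # structural zeros
        pri = GenePriors(beta_pi0=1.0)
        f0 = fit_negbin(y, d["X"], priors=pri, dispersion=2.0, zero_inflation=None)
        f5 = fit_negbin(y, d["X"], priors=pri, dispersion=2.0, zero_inflation=0.4)
        assert f5.log_marglik > f0.log_marglik

    def test_dispersion_estimator_order_of_magnitude(self, design_2x6, rng):
        d = design_2x6
        raws = []
        for _ in range(150):
            cn = rng.standard_normal(12)
            mu = np.exp(4.0 + 0.8 * cn)
            y = rng.negative_binomial(3.0, 3.0 / (3.0 + mu)).astype(float)
            raws.append(estimate_dispersion(y, d["lines"], cn=cn))
        moderated = moderate_dispersions(np.array(raws))
        med = np.median(moderated)
        assert 1.0 < med < 15.0  # true size 3, noisy MoM on 12 obs
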