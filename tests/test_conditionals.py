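"""Exact full conditionals against independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from outsel.model import ModelSpec, ModelState, NormalPrior, LogNormalPrior, SpikeSpec
from outsel.panel import PanelArrays
from outsel.sampler import (
    alpha_full_conditional,
    beta_full_conditional,
    gamma_full_conditional,
    indicator_probability,
    log_likelihood,
    mu_full_conditional,
    nu_full_conditional,
    update_beta_laplace,
    update_sigma,
)
from oracles import grid_moments, loglik_loop, normal_lik_times_normal_prior


def make_state(K, n, q=1, **kw):
    defaults = dict(
        beta=np.zeros(K),
        indicators=np.ones(K, dtype=np.int8),
        mu=0.0,
        tau=1.0,
        nu=np.zeros(K),
        gamma=np.zeros((q, K)),
        alpha=np.zeros(n),
        sigma=np.ones(K),
        sigma_r=1.0,
    )
    defaults.update(kw)
    return ModelState(**defaults)


def arrays_from(Y, exposure, Z=None, mask=None):
    Y = np.asarray(Y, dtype=float)
    n, K = Y.shape
    Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    mask = np.ones((n, K), dtype=bool) if mask is None else mask
    return PanelArrays(Y=Y, mask=mask, exposure=np.asarray(exposure, dtype=float),
                       Z=Z, n=n, K=K, z_cols=[f"z{a+1}" for a in range(Z.shape[1])])


class TestLogLikelihood:
    def test_single_standard_normal_row(self):
        arr = arrays_from([[0.0]], [0.0])
        state = make_state(1, 1, q=0)
        assert log_likelihood(state, arr) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_row_loop(self, rng):
        from conftest import make_long

        panel = make_long(5, 3, rng, q=2, missing=[(3, 2)])
        state = make_state(3, 5, q=2,
                           beta=rng.normal(size=3), nu=rng.normal(size=3),
                           gamma=rng.normal(size=(2, 3)), alpha=rng.normal(size=5),
                           sigma=rng.uniform(0.5, 2.0, size=3))
        assert log_likelihood(state, panel) == pytest.approx(loglik_loop(state, panel))

    def test_intercept_random_effect_tradeoff(self):
        # on a 1-individual, 1-outcome panel, nu + alpha is only identified
        # through the sum: shifting mass between them leaves the value fixed
        arr = arrays_from([[1.3]], [0.7])
        a = make_state(1, 1, q=0, nu=np.array([0.4]), alpha=np.array([0.2]))
        b = make_state(1, 1, q=0, nu=np.array([1.4]), alpha=np.array([-0.8]))
        assert log_likelihood(a, arr) == pytest.approx(log_likelihood(b, arr))

    def test_nonpositive_sigma_rejected(self):
        arr = arrays_from([[0.0]], [1.0])
        state = make_state(1, 1, q=0, sigma=np.array([0.0]))
        with pytest.raises(ValueError):
            log_likelihood(state, arr)


class TestBetaConditional:
    def test_textbook_single_row(self):
        # one row, e=1, sigma=1, residual 3, prior N(0,1) -> posterior N(1.5, 0.5)
        arr = arrays_from([[3.0]], [1.0])
        state = make_state(1, 1, q=0, tau=1.0, mu=0.0)
        spec = ModelSpec(variant="hierarchical")
        mean, var = beta_full_conditional(state, arr, spec)
        assert mean[0] == pytest.approx(1.5)
        assert var[0] == pytest.approx(0.5)
        # independent quadrature of likelihood x prior
        logpost = normal_lik_times_normal_prior(np.array([3.0]), np.array([1.0]), 1.0, 0.0, 1.0)
        gm, gv = grid_moments(logpost, -6, 9)
        assert mean[0] == pytest.approx(gm, abs=1e-6)
        assert var[0] == pytest.approx(gv, rel=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_randomized_instances_match_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 7)
        e = rng.normal(size=m)
        sigma = rng.uniform(0.5, 2.0)
        y = rng.normal(size=m)
        prior_mean, prior_var = rng.normal(), rng.uniform(0.3, 3.0)
        arr = arrays_from(y[:, None], e)
        state = make_state(1, m, q=0, mu=prior_mean, tau=math.sqrt(prior_var),
                           sigma=np.array([sigma]))
        mean, var = beta_full_conditional(state, arr, ModelSpec(variant="hierarchical"))
        logpost = normal_lik_times_normal_prior(y, e, sigma, prior_mean, prior_var)
        gm, gv = grid_moments(logpost, mean[0] - 10 * math.sqrt(var[0]),
                              mean[0] + 10 * math.sqrt(var[0]))
        assert mean[0] == pytest.approx(gm, abs=1e-6)
        assert var[0] == pytest.approx(gv, rel=1e-4)

    def test_no_rows_falls_back_to_prior(self):
        arr = arrays_from([[0.0, 1.0]], [1.0], mask=np.array([[False, True]]))
        state = make_state(2, 1, q=0, mu=-2.0, tau=0.7)
        mean, var = beta_full_conditional(state, arr, ModelSpec(variant="hierarchical"))
        assert mean[0] == pytest.approx(-2.0)
        assert var[0] == pytest.approx(0.49)

    def test_spike_prior_when_excluded(self):
        arr = arrays_from([[0.0]], [1.0], mask=np.array([[False]]))
        state = make_state(1, 1, q=0, mu=-2.0, tau=1.0,
                           indicators=np.zeros(1, dtype=np.int8))
        spec = ModelSpec(variant="ssvs_mean", spike=SpikeSpec(kind="scaled", c=100.0))
        mean, var = beta_full_conditional(state, arr, spec)
        assert mean[0] == pytest.approx(0.0)
        assert var[0] == pytest.approx(0.01)  # tau^2 / c


class TestIndicatorConditional:
    def test_certain_inclusion(self):
        p = indicator_probability(np.array([0.3]), 0.0, 1.0, np.array([1.0]), 0.01)
        assert p[0] == 1.0

    def test_at_origin_equals_one_over_one_plus_sqrt_c(self):
        # beta = mu = 0: densities differ only through the SDs, giving
        # 1 / (1 + sqrt(c)); c = 100 -> 1/11
        for c in [4.0, 100.0, 400.0]:
            tau = 1.3
            p = indicator_probability(np.array([0.0]), 0.0, tau, np.array([0.5]), tau**2 / c)
            # direct density evaluation oracle
            slab = stats.norm.pdf(0.0, 0.0, tau)
            spike = stats.norm.pdf(0.0, 0.0, tau / math.sqrt(c))
            assert p[0] == pytest.approx(slab / (slab + spike))
            assert p[0] == pytest.approx(1.0 / (1.0 + math.sqrt(c)))

    def test_separation_monotone_in_c(self):
        tau = 1.0
        ps = [indicator_probability(np.array([0.0]), 0.0, tau, np.array([0.5]), tau**2 / c)[0]
              for c in [10, 100, 1000]]
        assert ps[0] > ps[1] > ps[2]

    def test_deep_slab_limit(self):
        p = indicator_probability(np.array([-3.0]), -3.0, 1.0, np.array([0.5]), 1e-4)
        assert p[0] > 1 - 1e-10

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            indicator_probability(np.array([0.0]), 0.0, 1.0, np.array([1.2]), 0.01)


class TestMuConditional:
    def test_two_selected_betas(self):
        # tau=1, prior N(0,100), selected beta={2,4} -> N(6/2.01, 1/2.01)
        state = make_state(2, 1, q=0, beta=np.array([2.0, 4.0]), tau=1.0)
        spec = ModelSpec(variant="ssvs_mean")
        mean, var = mu_full_conditional(state, spec)
        assert mean == pytest.approx(6.0 / 2.01)
        assert var == pytest.approx(1.0 / 2.01)
        # quadrature oracle
        def logpost(m):
            return (stats.norm.logpdf([2.0, 4.0], m, 1.0).sum()
                    + stats.norm.logpdf(m, 0.0, 10.0))
        gm, gv = grid_moments(logpost, -5, 11)
        assert mean == pytest.approx(gm, abs=1e-5)
        assert var == pytest.approx(gv, rel=1e-4)

    def test_empty_slab_returns_prior(self):
        state = make_state(3, 1, q=0, indicators=np.zeros(3, dtype=np.int8))
        spec = ModelSpec(variant="ssvs_mean", mu_prior=NormalPrior(1.5, 2.0))
        mean, var = mu_full_conditional(state, spec)
        assert (mean, var) == (1.5, 2.0)

    def test_flat_prior_limit_is_selected_mean(self):
        state = make_state(4, 1, q=0, beta=np.array([1.0, 2.0, 5.0, -9.0]),
                           indicators=np.array([1, 1, 1, 0], dtype=np.int8), tau=0.5)
        spec = ModelSpec(variant="ssvs_mean", mu_prior=NormalPrior(0.0, 1e12))
        mean, _ = mu_full_conditional(state, spec)
        assert mean == pytest.approx((1.0 + 2.0 + 5.0) / 3, abs=1e-6)

    def test_rejected_for_variants_without_mu(self):
        state = make_state(2, 1, q=0)
        for variant in ("ssvs_null", "laplace"):
            with pytest.raises(ValueError):
                mu_full_conditional(state, ModelSpec(variant=variant))


class TestNuGammaConditional:
    def test_single_row_matches_quadrature(self):
        arr = arrays_from([[2.5]], [0.0])
        state = make_state(1, 1, q=0, sigma=np.array([1.3]))
        spec = ModelSpec(variant="hierarchical", nu_prior=NormalPrior(0.0, 2.0))
        mean, var = nu_full_conditional(state, arr, spec)
        logpost = normal_lik_times_normal_prior(np.array([2.5]), np.array([1.0]), 1.3, 0.0, 2.0)
        gm, gv = grid_moments(logpost, -6, 9)
        assert mean[0] == pytest.approx(gm, abs=1e-6)
        assert var[0] == pytest.approx(gv, rel=1e-4)

    def test_vague_prior_limit_recovers_least_squares(self, rng):
        n, K = 40, 2
        e = rng.normal(size=n)
        Z = rng.normal(size=(n, 1))
        Y = rng.normal(size=(n, K))
        arr = arrays_from(Y, e, Z=Z)
        state = make_state(K, n, q=1, sigma=np.array([1.0, 1.0]))
        spec = ModelSpec(variant="hierarchical", nu_prior=NormalPrior(0.0, 1e10),
                         gamma_prior=NormalPrior(0.0, 1e10))
        nu_mean, _ = nu_full_conditional(state, arr, spec)
        # conditional on gamma=0, the nu update is just the column mean
        np.testing.assert_allclose(nu_mean, Y.mean(axis=0), atol=1e-6)
        g_mean, _ = gamma_full_conditional(0, state, arr, spec)
        # conditional on nu=0, gamma is the ratio of cross moments
        expect = (Z[:, 0][:, None] * Y).sum(axis=0) / (Z[:, 0] ** 2).sum()
        np.testing.assert_allclose(g_mean, expect, atol=1e-6)


class TestAlphaConditional:
    def test_homoscedastic_shrinkage_formula(self, rng):
        n, K = 3, 4
        sigma, sigma_r = 1.4, 0.8
        Y = rng.normal(size=(n, K))
        arr = arrays_from(Y, np.zeros(n))
        state = make_state(K, n, q=0, sigma=np.full(K, sigma), sigma_r=sigma_r)
        mean, var = alpha_full_conditional(state, arr)
        shrink = K * sigma_r**2 / (K * sigma_r**2 + sigma**2)
        np.testing.assert_allclose(mean, shrink * Y.mean(axis=1), rtol=1e-10)
        np.testing.assert_allclose(var, 1.0 / (K / sigma**2 + 1.0 / sigma_r**2))

    def test_no_rows_prior_fallback(self):
        arr = arrays_from([[0.0], [1.0]], [0.0, 0.0],
                          mask=np.array([[False], [True]]))
        state = make_state(1, 2, q=0, sigma_r=0.6)
        mean, var = alpha_full_conditional(state, arr)
        assert mean[0] == 0.0 and var[0] == pytest.approx(0.36)

    def test_tiny_sigma_r_pins_alpha_to_zero(self, rng):
        Y = rng.normal(size=(4, 3)) + 10.0
        arr = arrays_from(Y, np.zeros(4))
        state = make_state(3, 4, q=0, sigma_r=1e-8)
        mean, var = alpha_full_conditional(state, arr)
        # the documented variance floor (1e-10) caps the attainable precision
        assert np.abs(mean).max() < 1e-5 and var.max() < 1e-9


class TestSigmaSlice:
    def test_mode_near_residual_rms_with_diffuse_prior(self, rng):
        n, K = 60, 1
        sigma_true = 1.7
        Y = sigma_true * rng.standard_normal((n, K))
        arr = arrays_from(Y, np.zeros(n))
        spec = ModelSpec(variant="hierarchical", sigma_k_prior=LogNormalPrior(0.0, 1e6))
        # numerical optimization oracle for the full-conditional mode
        sse = float((Y**2).sum())
        res = optimize.minimize_scalar(
            lambda ls: n * ls + 0.5 * sse * math.exp(-2 * ls), bounds=(-3, 3), method="bounded"
        )
        rms = math.sqrt(sse / n)
        assert math.exp(res.x) == pytest.approx(rms, rel=1e-4)
        # long-run slice draws concentrate near the mode
        state = make_state(K, n, q=0)
        rng2 = np.random.default_rng(5)
        draws = []
        for _ in range(400):
            update_sigma(state, arr, spec, rng2)
            draws.append(state.sigma[0])
        assert np.mean(draws) == pytest.approx(rms, rel=0.1)


class TestLaplaceUpdate:
    def test_prior_draws_without_data(self):
        # no observed rows: repeated transitions must leave Laplace(0, 1)
        # invariant; compare long-run draws to the analytic distribution
        arr = arrays_from([[0.0]], [1.0], mask=np.array([[False]]))
        spec = ModelSpec(variant="laplace")
        state = make_state(1, 1, q=0, beta=np.array([0.5]))
        rng = np.random.default_rng(17)
        draws = []
        for _ in range(4000):
            update_beta_laplace(state, arr, spec, rng)
            draws.append(state.beta[0])
        draws = np.asarray(draws)
        assert stats.kstest(draws, stats.laplace(scale=1.0).cdf).pvalue > 0.01
        assert draws.mean() == pytest.approx(0.0, abs=0.12)
        assert draws.var() == pytest.approx(2.0, rel=0.15)

    def test_data_overwhelms_prior(self, rng):
        n = 400
        e = rng.normal(1.0, 1.0, size=n)
        beta_true = 2.5
        Y = (beta_true * e + 0.3 * rng.standard_normal(n))[:, None]
        arr = arrays_from(Y, e)
        spec = ModelSpec(variant="laplace")
        state = make_state(1, n, q=0, sigma=np.array([0.3]))
        rng2 = np.random.default_rng(3)
        draws = []
        for _ in range(500):
            update_beta_laplace(state, arr, spec, rng2)
            draws.append(state.beta[0])
        ols = float((e @ Y[:, 0]) / (e @ e))
        assert np.mean(draws[100:]) == pytest.approx(ols, abs=0.02)

    def test_sign_symmetry(self):
        # flipping all residual signs flips the draw distribution
        e = np.ones(5)
        Y = np.array([1.0, 2.0, 1.5, 0.5, 1.2])[:, None]
        spec = ModelSpec(variant="laplace")
        means = []
        for sign in (1.0, -1.0):
            arr = arrays_from(sign * Y, e)
            state = make_state(1, 5, q=0)
            rng = np.random.default_rng(9)
            draws = []
            for _ in range(2000):
                update_beta_laplace(state, arr, spec, rng)
                draws.append(state.beta[0])
            means.append(np.mean(draws))
        # symmetry is distributional: posterior means agree up to MC error
        assert means[0] == pytest.approx(-means[1], abs=0.05)
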