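"""Likelihood correctness of the omics-specific decoders.

Oracles are independent scipy implementations: ``scipy.stats.nbinom`` in its
(n, p) parameterization with n = theta, p = theta / (theta + mu), plus direct
pmf summation for normalization.
"""

import numpy as np
import pytest
from scipy import stats

from sofusion import _autodiff as ad
from sofusion.decoders import (ADTDecoder, BernoulliDecoder, NBMixtureParams,
                               UniversalDecoder, ZINBDecoder, ZINBParams,
                               BernoulliParams, adt_params, atac_bce,
                               bernoulli_params, fit_gmm_prior,
                               generic_reconstruction_loss, nb_mixture_nll,
                               total_reconstruction_loss, zinb_nll,
                               zinb_params)


def nb_logpmf(x, mu, theta):
    return stats.nbinom.logpmf(x, theta, theta / (theta + mu))


def zinb_logpmf(x, pi, mu, theta):
    nb = nb_logpmf(x, mu, theta)
    out = np.log1p(-pi) + nb
    zero = np.logaddexp(np.log(pi), np.log1p(-pi) + nb_logpmf(0, mu, theta))
    return np.where(np.asarray(x) == 0, zero, out)


def random_zinb_params(rng, shape):
    return ZINBParams(pi=rng.uniform(0.05, 0.9, shape),
                      mu=rng.uniform(0.2, 20.0, shape),
                      theta=rng.uniform(0.3, 30.0, shape))


class TestZINB:
    def test_nll_matches_scipy_oracle_on_random_cases(self, rng):
        for _ in range(100):
            shape = (rng.integers(1, 4), rng.integers(1, 4))
            params = random_zinb_params(rng, shape)
            x = rng.poisson(3.0, size=shape).astype(float)
            expected = -zinb_logpmf(x, params.pi, params.mu, params.theta).sum()
            assert zinb_nll(x, params) == pytest.approx(expected, abs=1e-8)

    def test_pmf_sums_to_one_over_effective_support(self, rng):
        for _ in range(20):
            pi = rng.uniform(0.0, 0.9)
            mu = rng.uniform(0.5, 15.0)
            theta = rng.uniform(0.5, 20.0)
            xmax = int(stats.nbinom.ppf(1 - 1e-6, theta, theta / (theta + mu)))
            xs = np.arange(xmax + 1, dtype=float)
            total = np.exp(-np.array(
                [zinb_nll(np.array([x]), ZINBParams(
                    pi=np.array([pi]), mu=np.array([mu]),
                    theta=np.array([theta]))) for x in xs])).sum()
            assert 1 - 1e-4 <= total <= 1 + 1e-8

    def test_full_dropout_makes_zero_certain(self):
        params = ZINBParams(pi=np.array([1.0 - 1e-12]), mu=np.array([5.0]),
                            theta=np.array([2.0]))
        assert zinb_nll(np.array([0.0]), params) == pytest.approx(0.0, abs=1e-9)

    def test_no_dropout_reduces_to_plain_nb(self, rng):
        mu, theta = 4.0, 3.0
        xs = np.arange(51, dtype=float)
        params = ZINBParams(pi=np.full(51, 1e-300), mu=np.full(51, mu),
                            theta=np.full(51, theta))
        ours = np.array([zinb_nll(xs[i:i + 1], ZINBParams(
            pi=params.pi[i:i + 1], mu=params.mu[i:i + 1],
            theta=params.theta[i:i + 1])) for i in range(51)])
        np.testing.assert_allclose(ours, -nb_logpmf(xs, mu, theta), atol=1e-8)

    def test_large_theta_approaches_poisson(self):
        mu = 6.0
        x = np.arange(25, dtype=float)
        params = ZINBParams(pi=np.full(25, 1e-300), mu=np.full(25, mu),
                            theta=np.full(25, 1e6))
        ours = np.array([zinb_nll(x[i:i + 1], ZINBParams(
            pi=params.pi[i:i + 1], mu=params.mu[i:i + 1],
            theta=params.theta[i:i + 1])) for i in range(25)])
        np.testing.assert_allclose(ours, -stats.poisson.logpmf(x, mu), atol=1e-3)

    def test_negative_or_fractional_counts_rejected(self, rng):
        params = random_zinb_params(rng, (1, 1))
        with pytest.raises(ValueError):
            zinb_nll(np.array([[-1.0]]), params)
        with pytest.raises(ValueError):
            zinb_nll(np.array([[0.5]]), params)

    def test_zero_weight_heads_give_neutral_parameters(self):
        dec = ZINBDecoder(np.random.default_rng(0), latent_dim=3, n_features=2)
        for layer in (dec.trunk, dec.head_pi, dec.head_mu, dec.head_theta):
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        p = zinb_params(np.ones((4, 3)), dec)
        np.testing.assert_allclose(p.pi, 0.5)
        np.testing.assert_allclose(p.mu, 1.0)
        np.testing.assert_allclose(p.theta, 1.0)

    def test_params_always_in_valid_ranges(self, rng):
        dec = ZINBDecoder(np.random.default_rng(1), latent_dim=4, n_features=3)
        p = zinb_params(rng.normal(size=(10, 4)) * 50, dec)
        assert ((p.pi > 0) & (p.pi < 1)).all()
        assert (p.mu > 0).all() and (p.theta > 0).all()

    def test_mle_recovery_on_synthetic_draws(self):
        # minimize the NLL directly over (pi, mu, theta) on 5000 ZINB draws
        rng = np.random.default_rng(7)
        pi_true, mu_true, theta_true = 0.3, 4.0, 2.0
        n = 5000
        nb = rng.poisson(rng.gamma(theta_true, mu_true / theta_true, n))
        x = np.where(rng.random(n) < pi_true, 0, nb).astype(float)

        from scipy.optimize import minimize

        def nll(params):
            logit_pi, log_mu, log_theta = params
            p = ZINBParams(pi=np.full(n, 1 / (1 + np.exp(-logit_pi))),
                           mu=np.full(n, np.exp(log_mu)),
                           theta=np.full(n, np.exp(log_theta)))
            return zinb_nll(x, p)

        res = minimize(nll, x0=[0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
        pi_hat = 1 / (1 + np.exp(-res.x[0]))
        mu_hat = np.exp(res.x[1])
        assert abs(mu_hat - mu_true) / mu_true < 0.10
        assert abs(pi_hat - pi_true) < 0.05


class TestBernoulli:
    def test_perfect_prediction_gives_near_zero_loss(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.clip(x, 1e-7, 1 - 1e-7)
        assert atac_bce(x, BernoulliParams(p=p)) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_costs_ln2_per_entry(self):
        x = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0]])
        loss = atac_bce(x, BernoulliParams(p=np.full((2, 3), 0.5)))
        assert loss == pytest.approx(6 * np.log(2), abs=1e-10)

    def test_matches_hand_computed_sum(self, rng):
        x = (rng.random((4, 5)) > 0.5).astype(float)
        p = rng.uniform(0.1, 0.9, (4, 5))
        expected = -(x * np.log(p) + (1 - x) * np.log(1 - p)).sum()
        assert atac_bce(x, BernoulliParams(p=p)) == pytest.approx(expected, abs=1e-8)

    def test_non_binary_input_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            atac_bce(np.array([[2.0]]), BernoulliParams(p=np.array([[0.5]])))

    def test_zero_weights_give_half_and_logit_monotonicity(self, rng):
        dec = BernoulliDecoder(np.random.default_rng(0), latent_dim=2, n_features=1)
        for layer in (dec.trunk, dec.head_p):
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        p0 = bernoulli_params(np.zeros((1, 2)), dec).p
        np.testing.assert_allclose(p0, 0.5)
        dec.head_p.b.data[:] = 2.0
        assert bernoulli_params(np.zeros((1, 2)), dec).p > p0


class TestGMMPrior:
    def test_recovers_planted_background_mean(self):
        rng = np.random.default_rng(11)
        lo = rng.normal(1.0, 0.3, 1000)
        hi = rng.normal(4.0, 0.3, 1000)
        counts = np.round(np.expm1(np.r_[lo, hi])).clip(min=0)[:, None]
        m, s = fit_gmm_prior(counts, seed=0)
        # within 3 standard errors of the planted log-mean (se ~ 0.3/sqrt(1000))
        assert abs(m[0] - 1.0) < 0.1

    def test_single_cluster_returns_sample_mean(self):
        rng = np.random.default_rng(5)
        counts = np.round(np.expm1(rng.normal(2.0, 0.2, 1000))).clip(min=0)[:, None]
        m, _ = fit_gmm_prior(counts, seed=0)
        logged = np.log1p(counts)
        assert abs(m[0] - logged.mean()) < 0.2

    def test_constant_counts_use_fallback(self):
        counts = np.full((50, 2), 3.0)
        m, s = fit_gmm_prior(counts)
        expected = np.log1p(3.0)
        np.testing.assert_allclose(m, expected)
        np.testing.assert_allclose(s, 0.5 * expected + 0.1)


class TestNBMixture:
    def _decoder(self, seed=0, d=3, g=4):
        rng = np.random.default_rng(seed)
        prior = (np.zeros(d), np.ones(d))
        return ADTDecoder(rng, latent_dim=g, n_features=d, prior=prior)

    def test_foreground_exceeds_background_by_alpha_identity(self, rng):
        dec = self._decoder()
        p = adt_params(rng.normal(size=(6, 4)), dec)
        np.testing.assert_allclose(p.nu_f / p.nu_b, 1.0 + p.alpha_adt, rtol=1e-10)
        assert (p.nu_f >= p.nu_b).all()

    def test_sampling_reproducible_bitwise_with_fixed_seed(self, rng):
        dec = self._decoder()
        Z = rng.normal(size=(5, 4))
        a = adt_params(Z, dec, sample=True, rng=np.random.default_rng(3))
        b = adt_params(Z, dec, sample=True, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.nu_b, b.nu_b)

    def test_pure_background_matches_scipy_nb(self, rng):
        x = rng.poisson(4.0, size=(3, 2)).astype(float)
        nu_b = rng.uniform(1, 8, (3, 2))
        phi = rng.uniform(1, 10, 2)
        params = NBMixtureParams(nu_b=nu_b, nu_f=nu_b * 3,
                                 pi_adt=np.full((3, 2), 1 - 1e-12), phi=phi)
        expected = -nb_logpmf(x, nu_b, phi[None, :]).sum()
        assert nb_mixture_nll(x, params) == pytest.approx(expected, abs=1e-6)

    def test_pure_foreground_matches_scipy_nb(self, rng):
        x = rng.poisson(4.0, size=(3, 2)).astype(float)
        nu_b = rng.uniform(1, 8, (3, 2))
        phi = rng.uniform(1, 10, 2)
        params = NBMixtureParams(nu_b=nu_b, nu_f=nu_b * 3,
                                 pi_adt=np.full((3, 2), 1e-12), phi=phi)
        expected = -nb_logpmf(x, nu_b * 3, phi[None, :]).sum()
        assert nb_mixture_nll(x, params) == pytest.approx(expected, abs=1e-6)

    def test_equal_components_collapse_for_any_mixture_weight(self, rng):
        x = rng.poisson(5.0, size=(4, 3)).astype(float)
        nu = rng.uniform(1, 9, (4, 3))
        phi = rng.uniform(0.5, 5, 3)
        for pi in (0.2, 0.5, 0.8):
            params = NBMixtureParams(nu_b=nu, nu_f=nu,
                                     pi_adt=np.full((4, 3), pi), phi=phi)
            expected = -nb_logpmf(x, nu, phi[None, :]).sum()
            assert nb_mixture_nll(x, params) == pytest.approx(expected, abs=1e-8)

    def test_mixture_nll_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            shape = (rng.integers(1, 4), rng.integers(1, 3))
            x = rng.poisson(3.0, size=shape).astype(float)
            nu_b = rng.uniform(0.5, 5, shape)
            alpha = rng.uniform(0, 4, shape)
            pi = rng.uniform(0.05, 0.95, shape)
            phi = rng.uniform(0.5, 10, shape[1])
            params = NBMixtureParams(nu_b=nu_b, nu_f=(1 + alpha) * nu_b,
                                     pi_adt=pi, phi=phi)
            expected = -np.logaddexp(
                np.log(pi) + nb_logpmf(x, nu_b, phi[None, :]),
                np.log1p(-pi) + nb_logpmf(x, (1 + alpha) * nu_b, phi[None, :]),
            ).sum()
            assert nb_mixture_nll(x, params) == pytest.approx(expected, abs=1e-8)

    def test_mixture_pmf_sums_to_one(self, rng):
        nu_b, fold, pi, phi = 2.0, 4.0, 0.4, 3.0
        xmax = int(stats.nbinom.ppf(1 - 1e-6, phi, phi / (phi + nu_b * fold)))
        xs = np.arange(xmax + 1, dtype=float)
        pmf = np.exp(np.logaddexp(
            np.log(pi) + nb_logpmf(xs, nu_b, phi),
            np.log1p(-pi) + nb_logpmf(xs, nu_b * fold, phi)))
        nll = np.array([nb_mixture_nll(np.array([[x]]), NBMixtureParams(
            nu_b=np.array([[nu_b]]), nu_f=np.array([[nu_b * fold]]),
            pi_adt=np.array([[pi]]), phi=np.array([phi]))) for x in xs])
        np.testing.assert_allclose(np.exp(-nll), pmf, atol=1e-10)
        assert 1 - 1e-4 <= np.exp(-nll).sum() <= 1 + 1e-8

    def test_kl_term_adds_closed_form_gaussian_kl(self, rng):
        x = np.zeros((2, 1))
        base = NBMixtureParams(nu_b=np.ones((2, 1)), nu_f=np.ones((2, 1)),
                               pi_adt=np.full((2, 1), 0.5), phi=np.ones(1))
        plain = nb_mixture_nll(x, base)
        withkl = NBMixtureParams(
            nu_b=base.nu_b, nu_f=base.nu_f, pi_adt=base.pi_adt, phi=base.phi,
            m_b=np.full((2, 1), 0.3), sigma_b=np.full((2, 1), 0.5),
            m_prior=np.zeros(1), sigma_prior=np.ones(1))
        kl = (np.log(1.0 / 0.5) + (0.25 + 0.09) / 2.0 - 0.5) * 2
        assert nb_mixture_nll(x, withkl) == pytest.approx(plain + kl, abs=1e-10)


class TestUniversalDecoder:
    def test_uniform_prediction_costs_ln2_per_binary_entry(self, rng):
        dec = UniversalDecoder(np.random.default_rng(0), latent_dim=2, n_features=3)
        for layer in (dec.trunk, dec.head):
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        x = (rng.random((4, 3)) > 0.5).astype(float)
        loss = generic_reconstruction_loss(x, np.zeros((4, 2)), dec)
        assert loss == pytest.approx(12 * np.log(2), abs=1e-10)

    def test_out_of_range_targets_direct_to_preprocessing(self):
        dec = UniversalDecoder(np.random.default_rng(0), latent_dim=2, n_features=1)
        with pytest.raises(ValueError, match="preprocess_other"):
            generic_reconstruction_loss(np.array([[1.5]]), np.zeros((1, 2)), dec)


class TestTotalReconstruction:
    def test_single_term_is_identity(self):
        assert total_reconstruction_loss([3.5]) == 3.5

    def test_sum_of_active_modalities(self):
        assert total_reconstruction_loss({"rna": 1.0, "adt": 2.5}) == 3.5

    def test_no_active_modalities_errors(self):
        with pytest.raises(ValueError):
            total_reconstruction_loss([])


class TestNLLGradients:
    """Autodiff gradients of each likelihood vs finite differences."""

    @staticmethod
    def _fd_check(make_loss, values, rtol=1e-4):
        params = [ad.Parameter(v.copy()) for v in values]
        loss = make_loss(*params)
        loss.backward()
        for k, v in enumerate(values):
            flat = v.ravel()
            num = np.zeros_like(flat)
            for i in range(flat.size):
                orig = flat[i]
                for sign, store in ((1, "hi"), (-1, "lo")):
                    flat[i] = orig + sign * 1e-5
                    args = [ad.Tensor(values[j]) for j in range(len(values))]
                    val = float(make_loss(*args).data)
                    if sign == 1:
                        hi = val
                    else:
                        lo = val
                flat[i] = orig
                num[i] = (hi - lo) / 2e-5
            np.testing.assert_allclose(params[k].grad.ravel(), num, rtol=rtol,
                                       atol=1e-6)

    def test_zinb_nll_gradients(self, rng):
        from sofusion.decoders import _zinb_nll_core

        x = ad.Tensor(rng.poisson(3.0, size=(3, 2)).astype(float))
        vals = [rng.uniform(0.2, 0.8, (3, 2)), rng.uniform(1, 5, (3, 2)),
                rng.uniform(1, 5, (3, 2))]
        self._fd_check(lambda pi, mu, th: _zinb_nll_core(x, pi, mu, th), vals)

    def test_bce_gradients(self, rng):
        from sofusion.decoders import _bce_core

        x = ad.Tensor((rng.random((3, 2)) > 0.5).astype(float))
        self._fd_check(lambda p: _bce_core(x, p),
                       [rng.uniform(0.2, 0.8, (3, 2))])

    def test_nb_mixture_gradients(self, rng):
        from sofusion.decoders import _nb_mixture_nll_core

        x = ad.Tensor(rng.poisson(2.0, size=(2, 2)).astype(float))
        vals = [rng.uniform(1, 4, (2, 2)), rng.uniform(5, 9, (2, 2)),
                rng.uniform(0.2, 0.8, (2, 2)), rng.uniform(1, 5, (2,))]
        self._fd_check(
            lambda nb, nf, pi, phi: _nb_mixture_nll_core(x, nb, nf, pi, phi),
            vals)
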