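"""Beta estimation, Gibbs-prior fitting, Bayes factors, and local fdr."""

import json
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import ultrafdr as uf
from ultrafdr.entropic_fit import BayesFactorModel, BetaCoefficients, Route


def smooth_beta(spec, order, domain, loc=0.5, width=0.8):
    """Moments of a smooth (truncated-Gaussian) prior: strictly interior
    points of the moment space, where the dual optimum is finite."""
    nodes, weights = np.polynomial.legendre.leggauss(800)
    lo, hi = domain
    u = lo + (hi - lo) / 2 * (nodes + 1)
    w = (hi - lo) / 2 * weights * np.exp(-0.5 * ((u - loc) / width) ** 2)
    w /= w.sum()
    beta = np.array([float(np.dot(w, u ** n)) for n in range(order + 1)])
    return BetaCoefficients(spec, beta, np.zeros(order + 1), 10 ** 6)


class TestEstimateBeta:
    def test_beta0_is_one_and_pointmass_moments(self, rng):
        spec = uf.normal_family()
        samp = rng.normal(1.0, 1.0, 10 ** 5)
        beta = uf.estimate_beta(samp, spec, 4)
        assert beta.beta[0] == 1.0
        # point mass at delta* = 1 has beta_n = 1 for every n
        for n in range(1, 5):
            assert abs(beta.beta[n] - 1.0) < 3 * beta.se[n]

    def test_central_data_has_vanishing_odd_moments(self, rng):
        spec = uf.normal_family()
        beta = uf.estimate_beta(rng.normal(0.0, 1.0, 10 ** 5), spec, 3)
        assert abs(beta.beta[1]) < 3 * beta.se[1]
        assert abs(beta.beta[3]) < 3 * beta.se[3]

    def test_out_of_support_rejection(self):
        spec = uf.t_family(5)
        vals = np.concatenate([np.linspace(-0.9, 0.9, 200), [2.0, -3.0, np.nan]])
        beta = uf.estimate_beta(vals, spec, 2)
        assert beta.n_rejected == 3
        assert beta.n_samples == 200

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            uf.estimate_beta(np.linspace(-0.5, 0.5, 50), uf.t_family(5), 2)

    def test_superposition_moments_match_prior(self, rng):
        """beta_n estimated from mixture draws equals the prior moments."""
        spec = uf.normal_family()
        prior = uf.PriorSpec.point_masses(spec, {0.0: 0.8, 2.0: 0.2})
        ss = uf.sample_superposition(prior, 2 * 10 ** 5, 904)
        beta = uf.estimate_beta(ss.values, spec, 6)
        for n in range(1, 7):
            assert abs(beta.beta[n] - prior.moment(n)) < 3 * beta.se[n], n


class TestGibbsPotential:
    def test_value_at_zero_is_log_volume(self):
        spec = uf.normal_family()
        beta = BetaCoefficients(spec, np.array([1.0, 0.3, 0.5]), np.zeros(3), 1000)
        v, g = uf.gibbs_potential(np.zeros(2), beta, prior_domain=(-1, 1))
        assert v == pytest.approx(math.log(2.0))
        # gradient at the origin: uniform-prior moments minus beta
        assert g[0] == pytest.approx(0.0 - 0.3, abs=1e-12)
        assert g[1] == pytest.approx(1.0 / 3.0 - 0.5, abs=1e-12)

    def test_stationarity_at_fitted_optimum(self):
        spec = uf.normal_family()
        beta = smooth_beta(spec, 6, (-3, 3), loc=0.8, width=0.6)
        prior = uf.fit_gibbs_prior(beta, prior_domain=(-3, 3))
        _, g = uf.gibbs_potential(prior.dual.lam, beta, prior_domain=(-3, 3))
        assert np.max(np.abs(g)) < 1e-6

    def test_hessian_is_psd(self, rng):
        """Convexity: the Hessian is the monomial covariance under pi."""
        nodes, weights = np.polynomial.legendre.leggauss(400)
        lam = rng.normal(0, 0.5, 4)
        powers = np.stack([nodes ** n for n in range(1, 5)])
        tilt = lam @ powers
        pi = np.exp(tilt - logsumexp(tilt, b=weights)) * weights
        mom = powers @ pi
        H = (powers * pi) @ powers.T - np.outer(mom, mom)
        assert np.min(np.linalg.eigvalsh(H)) > -1e-12


class TestFitGibbsPrior:
    def test_uniform_moments_give_zero_dual(self):
        spec = uf.normal_family()
        mom = np.array([1.0] + [(1 - (-1) ** (n + 1)) / (2 * (n + 1)) for n in range(1, 6)])
        beta = BetaCoefficients(spec, mom, np.zeros(6), 1000)
        prior = uf.fit_gibbs_prior(beta, prior_domain=(-1, 1))
        assert np.max(np.abs(prior.dual.lam)) < 1e-6

    def test_interior_moments_residual_and_two_starts(self, rng):
        spec = uf.normal_family()
        beta = smooth_beta(spec, 8, (-4, 4), loc=1.0, width=0.9)
        p1 = uf.fit_gibbs_prior(beta, prior_domain=(-4, 4))
        assert p1.moment_residual < 1e-6
        p2 = uf.fit_gibbs_prior(beta, prior_domain=(-4, 4),
                                x0=rng.normal(0, 0.05, 8))
        assert np.max(np.abs(p1.dual.lam - p2.dual.lam)) < 1e-5

    def test_prior_normalization_and_positivity(self):
        spec = uf.normal_family()
        beta = smooth_beta(spec, 6, (-3, 3))
        prior = uf.fit_gibbs_prior(beta, prior_domain=(-3, 3))
        assert prior.masses.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(prior.density(prior.nodes) >= 0.0)

    def test_pointmass_data_recovery(self, rng):
        """Sampled point-mass moments sit on the moment-space boundary; the
        fit stops early but the prior concentrates on the atom."""
        spec = uf.normal_family()
        beta = uf.estimate_beta(rng.normal(1.0, 1.0, 2 * 10 ** 5), spec, 8)
        prior = uf.fit_gibbs_prior(beta, prior_domain=(-4, 4))
        assert abs(prior.mean() - 1.0) < 0.05
        m = prior.masses
        assert m[np.abs(prior.nodes - 1.0) < 0.25].sum() / m.sum() > 0.9

    def test_lambda0_is_not_a_free_parameter(self):
        """Appending a free lam_0 leaves the pinned optimum stationary:
        its partial derivative is E[u^0] - beta_0 = 0 identically."""
        spec = uf.normal_family()
        domain = (-2, 2)
        beta = smooth_beta(spec, 4, domain, loc=0.3, width=0.5)
        prior = uf.fit_gibbs_prior(beta, prior_domain=domain)
        nodes, weights = np.polynomial.legendre.leggauss(400)
        u = domain[0] + 2 * (nodes + 1)  # map to (-2, 2)
        u = -2 + 2 * (nodes + 1)
        w = 2 * weights

        def extended(lam_full):
            powers = np.stack([u ** n for n in range(0, 5)])
            tilt = lam_full @ powers
            lz = logsumexp(tilt, b=w)
            pi = np.exp(tilt - lz) * w
            return (powers @ pi) - beta.beta

        grad = extended(np.concatenate([[0.0], prior.dual.lam]))
        assert abs(grad[0]) < 1e-12          # identically zero component
        assert np.max(np.abs(grad)) < 1e-6   # full stationarity


class TestBayesFactor:
    def test_central_model_is_unity(self):
        spec = uf.normal_family()
        beta = BetaCoefficients(spec, np.array([1.0, 0, 0, 0]), np.zeros(4), 1000)
        model = BayesFactorModel(spec, Route.MOMENT, beta)
        r = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(uf.bayes_factor(model, r), 1.0, atol=1e-12)
        assert uf.pvalue_density(model, 0.3) == pytest.approx(1.0)
        assert uf.local_fdr(model, 0.3) == pytest.approx(0.5)

    def test_moment_route_resums_pointmass_translation_factor(self):
        """beta_n = 1^n resummed over 40 Hermite terms gives e^(r - 1/2)."""
        spec = uf.normal_family()
        beta = BetaCoefficients(spec, np.ones(41), np.zeros(41), 1000)
        model = BayesFactorModel(spec, Route.MOMENT, beta)
        assert uf.bayes_factor(model, 0.0) == pytest.approx(math.exp(-0.5), rel=1e-9)
        assert uf.pvalue_density(model, 0.5) == pytest.approx(math.exp(-0.5), rel=1e-9)
        r = np.array([-1.0, 0.5, 2.0])
        np.testing.assert_allclose(
            uf.bayes_factor(model, r),
            np.asarray(uf.translation_closed_form(spec, r, 1.0)), rtol=1e-6)

    def test_prior_route_matches_concentrated_translation_factor(self):
        """A Gibbs prior concentrated near u* reproduces T(r|u*)."""
        spec = uf.t_family(9)
        beta = BetaCoefficients(spec, 0.4 ** np.arange(9), np.zeros(9), 1000)
        prior = uf.fit_gibbs_prior(beta)
        model = BayesFactorModel(spec, Route.PRIOR, beta, prior)
        r = np.array([-0.6, 0.0, 0.6])
        ref = np.asarray(uf.translation_closed_form(spec, r, 0.4))
        np.testing.assert_allclose(uf.bayes_factor(model, r), ref, rtol=2e-2)

    def test_local_fdr_limits(self):
        spec = uf.normal_family()
        beta = BetaCoefficients(spec, np.array([1.0, 0, 0]), np.zeros(3), 1000)
        model = BayesFactorModel(spec, Route.MOMENT, beta)
        assert uf.local_fdr(model, 0.4) == pytest.approx(0.5)
        strong = BetaCoefficients(spec, np.ones(41), np.zeros(41), 1000)
        ms = BayesFactorModel(spec, Route.MOMENT, strong)
        assert uf.local_fdr(ms, 1 - 1e-9) < 0.01   # BF huge in the far tail
        # clipped-to-zero BF gives fdr exactly 1
        # beta_2 = 4 makes BF(0) = 1 + (4/2) He2(0) = -1, clipped to 0
        neg = BetaCoefficients(spec, np.array([1.0, 0, 4.0]), np.zeros(3), 1000)
        mn = BayesFactorModel(spec, Route.MOMENT, neg)
        assert uf.local_fdr(mn, 0.5) == pytest.approx(1.0)

    def test_pvalue_density_integrates_to_one(self, rng):
        """Change of variables: int BF(p) dp = int BF(r) w(r) dr = 1."""
        spec = uf.normal_family()
        prior = uf.PriorSpec.point_masses(spec, {0.0: 0.8, 2.0: 0.2})
        ss = uf.sample_superposition(prior, 10 ** 5, 77)
        model = uf.fit_model(ss.values, spec, order=8)
        pg = np.linspace(1e-4, 1 - 1e-4, 2001)
        dens = np.asarray(uf.pvalue_density(model, pg))
        assert np.trapezoid(dens, pg) == pytest.approx(1.0, abs=0.05)

    def test_route_equivalence_on_inner_support(self):
        """Prior and moment routes agree away from the support edges, where
        the direct Gegenbauer series is truncation-limited."""
        ss = uf.paired_t_fixture(10 ** 5, nu2=42, seed=7)
        model = uf.fit_model(ss.values, ss.spec, order=8)
        assert model.route is Route.PRIOR
        mm = BayesFactorModel(ss.spec, Route.MOMENT, model.beta, model.prior)
        inner = np.asarray(uf.quantile(ss.spec, np.linspace(0.05, 0.95, 21)))
        bf_p = np.asarray(uf.bayes_factor(model, inner))
        bf_m = np.asarray(uf.bayes_factor(mm, inner))
        assert np.max(np.abs(bf_p - bf_m) / bf_p) < 0.1


class TestModelFitKL:
    def test_central_self_consistency(self, rng):
        spec = uf.normal_family()
        samp = rng.normal(0.0, 1.0, 10 ** 5)
        beta = BetaCoefficients(spec, np.array([1.0, 0, 0]), np.zeros(3), 1000)
        model = BayesFactorModel(spec, Route.MOMENT, beta)
        assert uf.model_fit_kl(samp, model, bins=200) < 0.01

    def test_kl_decreases_with_order(self):
        spec = uf.normal_family()
        prior = uf.PriorSpec.point_masses(spec, {0.0: 0.8, 2.0: 0.2})
        ss = uf.sample_superposition(prior, 2 * 10 ** 5, 11)
        beta = uf.estimate_beta(ss.values, spec, 8)
        kl2 = uf.model_fit_kl(ss.values, BayesFactorModel(spec, Route.MOMENT, beta.truncated(2)))
        kl8 = uf.model_fit_kl(ss.values, BayesFactorModel(spec, Route.MOMENT, beta))
        assert kl8 <= kl2


class TestSerialization:
    def test_roundtrip_preserves_bayes_factors(self, rng):
        spec = uf.normal_family()
        prior = uf.PriorSpec.point_masses(spec, {0.0: 0.7, 1.5: 0.3})
        ss = uf.sample_superposition(prior, 5 * 10 ** 4, 5)
        model = uf.fit_model(ss.values, spec, order=6)
        text = uf.model_to_json(model)
        doc = json.loads(text)
        assert doc["family"] == "normal" and doc["order"] == 6
        back = uf.model_from_json(text)
        r = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(np.asarray(uf.bayes_factor(back, r)),
                                   np.asarray(uf.bayes_factor(model, r)), rtol=1e-8)
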