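"""Closed-form oracles for every log-density contribution of the model."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from submort._corr import correlation_from_cpc_z, sample_lkj_cpc
from submort.basis import PCBasis
from submort.data import MortalityDataset
from submort.model import (
    ModelConfig,
    ModelParams,
    beta_prior_logdensity,
    gamma_prior_logdensity,
    joint_logdensity,
    likelihood_logdensity,
    log_rate,
    poisson_loglik,
    rw2_logdensity,
    sigma_mu_prior_logdensity,
)

LOG2PI = np.log(2 * np.pi)


def _toy_basis(A=4, P=4, seed=0):
    rng = np.random.default_rng(seed)
    comps = rng.normal(size=(A, P))
    return PCBasis(
        components=comps, singular_values=np.ones(P), left_values=np.eye(P)
    )


class TestLogRate:
    def test_zero_coefficients_give_unit_rate(self):
        basis = _toy_basis()
        assert log_rate(np.zeros(4), basis, 0.0, age=2) == 0.0

    def test_unit_vector_selects_component(self):
        basis = _toy_basis()
        for a in range(4):
            got = log_rate(np.array([1.0, 0, 0, 0]), basis, 0.0, age=a)
            assert got == pytest.approx(basis.components[a, 0])

    def test_matches_elementwise_loop(self):
        basis = _toy_basis()
        beta = np.array([0.5, -0.2, 0.1, 0.3])
        expected = sum(beta[i] * basis.components[1, i] for i in range(4)) + 0.05
        assert log_rate(beta, basis, 0.05, age=1) == pytest.approx(expected)


class TestPoissonLoglik:
    def test_zero_count_is_minus_mean(self):
        assert poisson_loglik(0, 50.0, 0.04) == pytest.approx(-2.0)

    def test_hand_computed_pmf(self):
        # y=3, mean 2: 3 ln 2 - 2 - ln 6
        expected = 3 * np.log(2) - 2 - np.log(6)
        assert poisson_loglik(3, 100.0, 0.02) == pytest.approx(expected)
        assert expected == pytest.approx(-1.7123, abs=1e-4)

    def test_empty_cell_contributes_zero(self):
        assert poisson_loglik(0, 0.0, 0.01) == 0.0

    def test_deaths_without_exposure_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(2, 0.0, 0.01)


def _params(
    omega, L_beta, sigma_beta, mu_beta=None, gamma=None, L_gamma=None,
    sigma_gamma=None, sigma_mu=None, A=1
):
    P, S, C, T = omega.shape
    if gamma is None:
        gamma = np.zeros((A, S, C, T))
    A = gamma.shape[0]
    return ModelParams(
        mu_beta=np.zeros((P, S, T)) if mu_beta is None else mu_beta,
        omega=omega,
        sigma_beta=sigma_beta,
        L_beta=L_beta,
        sigma_mu=np.full(P, 0.2) if sigma_mu is None else sigma_mu,
        gamma=gamma,
        sigma_gamma=np.full(A, 0.1) if sigma_gamma is None else sigma_gamma,
        L_gamma=np.broadcast_to(np.eye(S), (A, T, S, S)).copy()
        if L_gamma is None
        else L_gamma,
    )


class TestBetaPrior:
    def test_standard_normal_at_origin(self):
        # S=2, L=I, sigma=1, omega=0: MVN part is 2 * (-0.5 log 2pi);
        # the only other contribution is the half-normal density at sigma=1
        omega = np.zeros((1, 2, 1, 1))
        L = np.eye(2)[None, None]
        params = _params(omega, L, np.ones((1, 1, 1)))
        got = beta_prior_logdensity(params, ModelConfig(n_components=1))
        expected = 2 * (-0.5 * LOG2PI) + stats.halfnorm.logpdf(1.0, scale=1.0)
        assert got == pytest.approx(expected)

    def test_bivariate_closed_form(self):
        rho = 0.5
        omega = np.ones((1, 2, 1, 1))
        L = np.linalg.cholesky(np.array([[1, rho], [rho, 1]]))[None, None]
        params = _params(omega, L.copy(), np.ones((1, 1, 1)))
        got = beta_prior_logdensity(params, ModelConfig(n_components=1))
        # closed form with determinant 1 - rho^2 at x = (1, 1)
        quad_form = (1 - 2 * rho + 1) / (1 - rho**2)
        mvn = -0.5 * quad_form - 0.5 * np.log(1 - rho**2) - LOG2PI
        lkj = 0.0  # eta=1, S=2: exponent of L_22 is zero
        hn = stats.halfnorm.logpdf(1.0, scale=1.0)
        assert got == pytest.approx(mvn + lkj + hn)

    def test_lkj1_marginal_is_uniform_for_two_groups(self, rng):
        # LKJ(1), S=2: the off-diagonal correlation is uniform on (-1, 1)
        z = sample_lkj_cpc(2, 1.0, 10_000, rng)
        R = correlation_from_cpc_z(z, 2)
        r = R[:, 1, 0]
        ks = stats.kstest(r, stats.uniform(loc=-1, scale=2).cdf)
        assert ks.pvalue > 1e-3


class TestRW2:
    def test_linear_series_is_fully_smooth(self):
        t = np.arange(6)
        mu = 0.7 - 0.3 * t
        sigma = 0.4
        got = rw2_logdensity(mu, sigma)
        assert got == pytest.approx(4 * stats.norm.logpdf(0.0, scale=sigma))

    def test_single_step_hand_value(self):
        got = rw2_logdensity(np.array([0.0, 0.0, 1.0]), 1.0)
        assert got == pytest.approx(-0.5 * LOG2PI - 0.5)

    def test_short_series_are_flat(self):
        assert rw2_logdensity(np.array([3.0, -1.0]), 0.5) == 0.0
        assert rw2_logdensity(np.array([3.0]), 0.5) == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rw2_logdensity(np.array([]), 0.5)


class TestGammaPrior:
    def test_zero_vector_is_mode(self):
        S, A, T = 2, 1, 1
        gamma = np.zeros((A, S, 1, T))
        params = _params(
            np.zeros((1, S, 1, T)), np.eye(S)[None, None], np.ones((1, 1, 1)),
            gamma=gamma, sigma_gamma=np.array([0.25]),
        )
        got = gamma_prior_logdensity(params, ModelConfig(n_components=1))
        mvn_mode = 2 * stats.norm.logpdf(0.0, scale=0.25)
        hn = stats.halfnorm.logpdf(0.25, scale=0.25)
        assert got == pytest.approx(mvn_mode + hn)

    def test_independence_factorizes(self):
        # rho = 0, sigma_a = 0.25, gamma = (0.25, -0.25): two univariate
        # normal densities at plus/minus one standard deviation
        gamma = np.array([0.25, -0.25]).reshape(1, 2, 1, 1)
        params = _params(
            np.zeros((1, 2, 1, 1)), np.eye(2)[None, None], np.ones((1, 1, 1)),
            gamma=gamma, sigma_gamma=np.array([0.25]),
        )
        got = gamma_prior_logdensity(params, ModelConfig(n_components=1))
        uni = stats.norm.logpdf(0.25, scale=0.25) + stats.norm.logpdf(-0.25, scale=0.25)
        hn = stats.halfnorm.logpdf(0.25, scale=0.25)
        assert got == pytest.approx(uni + hn)

    def test_halfnormal_prior_normalized(self):
        total, _ = quad(lambda x: stats.halfnorm.pdf(x, scale=0.25), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestJointDensity:
    def _tiny_instance(self, seed=3):
        rng = np.random.default_rng(seed)
        A, S, C, T, P = 2, 2, 1, 3, 1
        expo = rng.uniform(100, 1000, size=(A, S, C, T))
        deaths = rng.poisson(expo * 0.01)
        data = MortalityDataset(
            deaths=deaths, exposures=expo,
            ages=["young", "old"], subpops=["f", "m"], areas=["c1"],
            years=[1, 2, 3],
        )
        basis = PCBasis(
            components=rng.normal(size=(A, P)),
            singular_values=np.ones(P),
            left_values=np.eye(P),
        )
        L = np.linalg.cholesky(np.array([[1.0, 0.3], [0.3, 1.0]]))
        params = ModelParams(
            mu_beta=rng.normal(size=(P, S, T)),
            omega=0.1 * rng.normal(size=(P, S, C, T)),
            sigma_beta=np.full((P, 1, T), 0.3),
            L_beta=np.broadcast_to(L, (P, T, S, S)).copy(),
            sigma_mu=np.array([0.2]),
            gamma=0.05 * rng.normal(size=(A, S, C, T)),
            sigma_gamma=np.array([0.1, 0.15]),
            L_gamma=np.broadcast_to(L, (A, T, S, S)).copy(),
        )
        return data, basis, params, ModelConfig(n_components=P)

    def test_decomposes_into_documented_parts(self):
        data, basis, params, cfg = self._tiny_instance()
        P, S, T = params.mu_beta.shape
        parts = likelihood_logdensity(data, basis, params)
        parts += beta_prior_logdensity(params, cfg)
        for i in range(P):
            for s in range(S):
                parts += rw2_logdensity(params.mu_beta[i, s], params.sigma_mu[i])
        parts += sigma_mu_prior_logdensity(params.sigma_mu, cfg)
        parts += gamma_prior_logdensity(params, cfg)
        assert joint_logdensity(data, basis, params, cfg) == pytest.approx(parts)

    def test_gamma_doubling_changes_only_gamma_terms(self):
        data, basis, params, cfg = self._tiny_instance()
        doubled = self._tiny_instance()[2]
        doubled.gamma = 2 * params.gamma
        delta = joint_logdensity(data, basis, doubled, cfg) - joint_logdensity(
            data, basis, params, cfg
        )
        expected = (
            likelihood_logdensity(data, basis, doubled)
            - likelihood_logdensity(data, basis, params)
            + gamma_prior_logdensity(doubled, cfg)
            - gamma_prior_logdensity(params, cfg)
        )
        assert delta == pytest.approx(expected)

    def test_zero_deaths_likelihood_is_negative_total_mean(self):
        data, basis, params, cfg = self._tiny_instance()
        data = MortalityDataset(
            deaths=np.zeros_like(data.deaths), exposures=data.exposures,
            ages=data.ages, subpops=data.subpops, areas=data.areas,
            years=data.years,
        )
        P = params.mu_beta.shape[0]
        loglam = (
            np.einsum("ai,isct->asct", basis.components[:, :P], params.beta)
            + params.gamma
        )
        expected = -np.sum(data.exposures * np.exp(loglam))
        assert likelihood_logdensity(data, basis, params) == pytest.approx(expected)

    def test_beta_equals_mean_plus_deviation(self):
        _, _, params, _ = self._tiny_instance()
        assert np.array_equal(
            params.beta, params.mu_beta[:, :, None, :] + params.omega
        )
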