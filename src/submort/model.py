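"""Joint probability model for mortality rates across correlated subpopulations.

The observed death count in each (age a, subpopulation s, area c, year t)
cell is Poisson with mean exposure times rate.  The log rate is a linear
combination of P principal-component age schedules plus an age-specific
overdispersion term:

    log lambda_{a,s,c,t} = sum_i beta_{i,s,c,t} Y_{i,a} + gamma_{a,s,c,t}

Coefficients decompose into an area-group mean and an area deviation,
beta = mu_beta + omega.  Across the S subpopulations of an area, deviations
omega (per component) and overdispersion gamma (per age) are multivariate
normal with covariance sigma^2 * R where R = L L' is a correlation matrix
with an LKJ(1) prior — this is where mortality information is shared between
subpopulations.  Group-level means mu_beta are smoothed over time by a
second-order random walk.

This module holds the model's configuration, parameter container, and every
log-density contribution in plain (constrained) parameter space.  The
inference module samples an equivalent unconstrained, non-centred
reparameterization; the functions here are the readable reference form used
directly by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import numpy as np
from scipy import stats

from ._corr import lkj_logdensity  # noqa: F401  (re-exported for convenience)
from .basis import PCBasis
from .data import MortalityDataset


@dataclass
class ModelConfig:
    """Model structure flags and hyperprior constants.

    The hyperprior constants default to the values the model is defined
    with: sigma_beta ~ half-normal(0, 1) per (component, year);
    sigma_mu ~ log-normal(-1.5, 0.5) per component; sigma_gamma ~
    half-normal(0, 0.25) per age group; LKJ(1) on every correlation matrix.
    Half-normal scales are scale parameters (not variances).
    """

    n_components: int = 4
    share_beta_corr_over_time: bool = False
    share_gamma_corr_over_time: bool = False
    subpop_specific_sigma_beta: bool = False
    fix_identity_corr: bool = False  # ablation: no cross-subpopulation pooling
    sigma_beta_scale: float = 1.0
    sigma_mu_logloc: float = -1.5
    sigma_mu_logscale: float = 0.5
    sigma_gamma_scale: float = 0.25
    lkj_eta: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ModelParams:
    """All latent quantities, in constrained space.

    Shapes (P components, S subpops, C areas, T years, A ages):
    mu_beta (P,S,T); omega (P,S,C,T); sigma_beta (P,1,T) or (P,S,T);
    L_beta (P,T,S,S); sigma_mu (P,); gamma (A,S,C,T); sigma_gamma (A,);
    L_gamma (A,T,S,S).  ``beta`` is derived: mu_beta broadcast over areas
    plus omega, so the decomposition identity holds by construction.
    """

    mu_beta: np.ndarray
    omega: np.ndarray
    sigma_beta: np.ndarray
    L_beta: np.ndarray
    sigma_mu: np.ndarray
    gamma: np.ndarray
    sigma_gamma: np.ndarray
    L_gamma: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return self.mu_beta[:, :, None, :] + self.omega

    def validate(self) -> None:
        for name in ("sigma_beta", "sigma_mu", "sigma_gamma"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for L in (self.L_beta, self.L_gamma):
            R = L @ np.swapaxes(L, -1, -2)
            if not np.allclose(np.diagonal(R, axis1=-2, axis2=-1), 1.0, atol=1e-8):
                raise ValueError("correlation factors must have unit-diagonal L L'")


def log_rate(beta_vec: np.ndarray, basis: PCBasis, gamma_val: float, age: int) -> float:
    """Log mortality rate at one cell: sum_i beta_i Y_{i,age} + gamma."""
    beta_vec = np.asarray(beta_vec, dtype=float)
    P = beta_vec.shape[0]
    if basis.n_components < P:
        raise ValueError("basis has fewer components than beta")
    return float(basis.components[age, :P] @ beta_vec + gamma_val)


def log_rate_array(beta: np.ndarray, components: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Vectorized linear predictor over the full (A,S,C,T) grid."""
    return np.einsum("ai,isct->asct", components, beta) + gamma


def poisson_loglik(y: float, exposure: float, lam: float) -> float:
    """Poisson log pmf with mean exposure*lam; empty (0,0) cells contribute 0."""
    if exposure < 0:
        raise ValueError("exposure must be non-negative")
    if exposure == 0:
        if y > 0:
            raise ValueError("positive deaths with zero exposure")
        return 0.0
    if lam <= 0:
        raise ValueError("rate must be positive")
    return float(stats.poisson.logpmf(y, exposure * lam))


def _mvn_logpdf_chol(x: np.ndarray, scale: np.ndarray, L: np.ndarray) -> float:
    """MVN(0, diag(scale) L L' diag(scale)) log density, batched over rows of x.

    x: (..., S); scale: broadcastable to (..., S); L: (..., S, S).
    """
    from scipy.linalg import solve_triangular

    S = x.shape[-1]
    x = np.atleast_2d(x)
    Lfull = np.broadcast_to(L, x.shape + (S,))
    scl = np.broadcast_to(scale, x.shape)
    total = 0.0
    for idx in np.ndindex(x.shape[:-1]):
        xi = x[idx] / scl[idx]
        zi = solve_triangular(Lfull[idx], xi, lower=True)
        logdet = np.sum(np.log(np.abs(np.diagonal(Lfull[idx])))) + np.sum(
            np.log(scl[idx])
        )
        total += -0.5 * zi @ zi - logdet - 0.5 * S * np.log(2 * np.pi)
    return float(total)


def lkj_cholesky_logdensity(L: np.ndarray, eta: float = 1.0) -> float:
    """Unnormalized LKJ(eta) log density of a correlation Cholesky factor.

    sum_{k=2..S} (S - k + 2 eta - 2) log L_kk; for eta = 1 the density over
    correlation matrices is uniform and this term is the volume element of
    the Cholesky parameterization.
    """
    S = L.shape[-1]
    k = np.arange(1, S)  # 0-indexed rows 1..S-1 are 1-indexed k=2..S
    expo = S - (k + 1) + 2.0 * eta - 2.0
    diag = np.diagonal(L, axis1=-2, axis2=-1)[..., 1:]
    return float(np.sum(expo * np.log(diag)))


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> float:
    return float(np.sum(stats.halfnorm.logpdf(x, scale=scale)))


def beta_prior_logdensity(params: ModelParams, config: ModelConfig) -> float:
    """Log density of the correlated county-deviation block.

    For every (component i, area c, year t), the S-vector omega_{i,.,c,t} is
    MVN(0, sigma_{i,t}^2 R_{i,t}); plus LKJ(eta) on each correlation factor
    and half-normal on each sigma_beta.
    """
    P, S, C, T = params.omega.shape
    total = 0.0
    sig = params.sigma_beta  # (P, 1 or S, T)
    for i in range(P):
        for t in range(T):
            L = params.L_beta[i, t]
            scale = np.broadcast_to(sig[i, :, t], (S,))
            x = params.omega[i, :, :, t].T  # (C, S)
            total += _mvn_logpdf_chol(x, scale, L)
    if not config.fix_identity_corr:
        Ls = (
            params.L_beta[:, :1]
            if config.share_beta_corr_over_time
            else params.L_beta
        )
        for L in Ls.reshape(-1, S, S):
            total += lkj_cholesky_logdensity(L, config.lkj_eta)
    total += _halfnormal_logpdf(params.sigma_beta, config.sigma_beta_scale)
    return total


def rw2_logdensity(mu_series: np.ndarray, sigma: float) -> float:
    """Second-order random-walk log density of one time series.

    Flat (improper, zero-contribution) priors on the first two time points;
    each later point is normal around the linear extrapolation
    2 mu_{t-1} - mu_{t-2} with scale ``sigma``.  The hyperprior on ``sigma``
    is accounted for once per component in :func:`joint_logdensity`, not here.
    """
    mu_series = np.asarray(mu_series, dtype=float)
    if mu_series.ndim != 1 or mu_series.size < 1:
        raise ValueError("mu_series must be a non-empty 1-d array")
    if mu_series.size < 3:
        return 0.0
    r = np.diff(mu_series, n=2)
    return float(np.sum(stats.norm.logpdf(r, loc=0.0, scale=sigma)))


def sigma_mu_prior_logdensity(sigma_mu: np.ndarray, config: ModelConfig) -> float:
    """log-Normal(loc, scale) hyperprior on the RW2 innovation scales."""
    return float(
        np.sum(
            stats.lognorm.logpdf(
                sigma_mu, s=config.sigma_mu_logscale,
                scale=np.exp(config.sigma_mu_logloc),
            )
        )
    )


def gamma_prior_logdensity(params: ModelParams, config: ModelConfig) -> float:
    """Log density of the correlated overdispersion block.

    For every (age a, area c, year t) the S-vector gamma_{a,.,c,t} is
    MVN(0, sigma_a^2 R_{a,t}); sigma_a is age-specific and shared across
    subpopulations, areas and years; plus LKJ(eta) per correlation factor
    and half-normal(0, 0.25) per sigma_a.
    """
    A, S, C, T = params.gamma.shape
    total = 0.0
    for a in range(A):
        for t in range(T):
            L = params.L_gamma[a, t]
            x = params.gamma[a, :, :, t].T
            total += _mvn_logpdf_chol(x, np.full(S, params.sigma_gamma[a]), L)
    if not config.fix_identity_corr:
        Ls = (
            params.L_gamma[:, :1]
            if config.share_gamma_corr_over_time
            else params.L_gamma
        )
        for L in Ls.reshape(-1, S, S):
            total += lkj_cholesky_logdensity(L, config.lkj_eta)
    total += _halfnormal_logpdf(params.sigma_gamma, config.sigma_gamma_scale)
    return total


def likelihood_logdensity(
    data: MortalityDataset, basis: PCBasis, params: ModelParams
) -> float:
    """Poisson log likelihood over all unmasked cells with positive exposure."""
    P = params.mu_beta.shape[0]
    loglam = log_rate_array(params.beta, basis.components[:, :P], params.gamma)
    m = data.mask
    return float(
        np.sum(stats.poisson.logpmf(data.deaths[m], data.exposures[m] * np.exp(loglam[m])))
    )


def joint_logdensity(
    data: MortalityDataset,
    basis: PCBasis,
    params: ModelParams,
    config: ModelConfig,
) -> float:
    """Full log posterior density (up to the normalizing constant).

    The sum of four blocks: the Poisson likelihood; the beta block
    (correlated deviations + LKJ + half-normal scales); the temporal block
    (RW2 over every component-subpopulation mean series + log-normal
    hyperprior on its scales); and the gamma block.
    """
    P, S, T = params.mu_beta.shape
    total = likelihood_logdensity(data, basis, params)
    total += beta_prior_logdensity(params, config)
    for i in range(P):
        for s in range(S):
            total += rw2_logdensity(params.mu_beta[i, s], params.sigma_mu[i])
    total += sigma_mu_prior_logdensity(params.sigma_mu, config)
    total += gamma_prior_logdensity(params, config)
    return total
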