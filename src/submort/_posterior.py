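"""Unconstrained, non-centred posterior density with analytic gradient.

The sampler works on a flat real vector theta packing, in order:

  mu_beta   (P,S,T)        group-level means (sampled directly; RW2 prior)
  lsm       (P,)           log sigma_mu
  z_omega   (P,S,C,T)      standard-normal innovations; omega = sigma * L z
  lsb       (P,Sb,T)       log sigma_beta (Sb = S if subpop-specific else 1)
  y_Lb      (P,Tb,M)       CPCs of the beta correlation Cholesky factors
  z_gamma   (A,S,C,T)      innovations; gamma = sigma_a * L z
  lsg       (A,)           log sigma_gamma
  y_Lg      (A,Tg,M)       CPCs of the gamma correlation factors

with M = S(S-1)/2, Tb/Tg = 1 when correlations are shared over time.
Scale parameters are sampled on the log scale with the Jacobian folded into
the density, and the hierarchical vectors are non-centred: with sparse data
the joint geometry of (scale, deviations) is a funnel, and non-centring
makes it close to isotropic for NUTS.

``logp_grad`` returns the log posterior kernel (additive constants dropped)
and its exact gradient; correctness is pinned down by finite-difference
tests against :mod:`submort.model`.
"""

from __future__ import annotations

import numpy as np

from ._corr import (
    cholesky_backward,
    cpc_to_cholesky,
    lkj_grad,
    lkj_logdensity,
    n_cpc,
)
from .data import MortalityDataset
from .model import ModelConfig, ModelParams


class PosteriorDensity:
    """Log posterior kernel and gradient for one dataset/basis/config."""

    def __init__(
        self,
        data: MortalityDataset,
        components: np.ndarray,
        config: ModelConfig,
    ):
        A, S, C, T = data.shape
        P = config.n_components
        if components.shape[0] != A:
            raise ValueError("basis age dimension does not match data")
        if components.shape[1] < P:
            raise ValueError("basis has fewer components than the model needs")
        if S < 2:
            raise ValueError("need at least two subpopulations")
        self.data = data
        self.Y = np.ascontiguousarray(components[:, :P], dtype=float)
        self.config = config
        self.A, self.S, self.C, self.T, self.P = A, S, C, T, P
        self.M = n_cpc(S)
        self.Sb = S if config.subpop_specific_sigma_beta else 1
        self.Tb = 1 if config.share_beta_corr_over_time else T
        self.Tg = 1 if config.share_gamma_corr_over_time else T
        self.identity_corr = config.fix_identity_corr

        shapes = {
            "mu_beta": (P, S, T),
            "lsm": (P,),
            "z_omega": (P, S, C, T),
            "lsb": (P, self.Sb, T),
        }
        if not self.identity_corr:
            shapes["y_Lb"] = (P, self.Tb, self.M)
        shapes["z_gamma"] = (A, S, C, T)
        shapes["lsg"] = (A,)
        if not self.identity_corr:
            shapes["y_Lg"] = (A, self.Tg, self.M)
        self._shapes = shapes
        self._slices = {}
        off = 0
        for k, shp in shapes.items():
            size = int(np.prod(shp))
            self._slices[k] = slice(off, off + size)
            off += size
        self.n_params = off

        self._eye_b = np.broadcast_to(np.eye(S), (P, self.T, S, S))
        self._eye_g = np.broadcast_to(np.eye(S), (A, self.T, S, S))
        self._tril = np.tril(np.ones((S, S)))
        self._mask = data.mask
        self._y = data.deaths.astype(float)
        self._expo = data.exposures
        self._ym = np.where(self._mask, self._y, 0.0)
        self._em = np.where(self._mask, self._expo, 0.0)

    # -- packing ----------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {
            k: theta[self._slices[k]].reshape(shp)
            for k, shp in self._shapes.items()
        }

    def pack(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        theta = np.empty(self.n_params)
        for k, shp in self._shapes.items():
            theta[self._slices[k]] = np.asarray(blocks[k], dtype=float).ravel()
        return theta

    # -- deterministic transforms -----------------------------------------
    def _chol_factors(self, y_L: np.ndarray | None, n_row: int, Tshare: int):
        """(n_row, Tshare, M) CPCs -> (n_row, T, S, S) Cholesky factors."""
        if self.identity_corr or y_L is None:
            L = np.broadcast_to(np.eye(self.S), (n_row, self.T, self.S, self.S))
            return np.ascontiguousarray(L)
        L = cpc_to_cholesky(y_L.reshape(n_row * Tshare, self.M), self.S)
        L = L.reshape(n_row, Tshare, self.S, self.S)
        if Tshare == 1:
            L = np.broadcast_to(L, (n_row, self.T, self.S, self.S))
        return np.ascontiguousarray(L)

    def constrain(self, theta: np.ndarray) -> ModelParams:
        """Constrained :class:`ModelParams` for one draw of theta."""
        b = self.unpack(theta)
        Lb = self._chol_factors(b.get("y_Lb"), self.P, self.Tb)
        Lg = self._chol_factors(b.get("y_Lg"), self.A, self.Tg)
        sigma_b = np.exp(b["lsb"])  # (P,Sb,T)
        sb_full = np.broadcast_to(sigma_b, (self.P, self.S, self.T)) \
            if self.Sb == 1 else sigma_b
        Lz = np.einsum("ptsu,puct->psct", Lb, b["z_omega"])
        omega = sb_full[:, :, None, :] * Lz
        sigma_g = np.exp(b["lsg"])
        Lgz = np.einsum("atsu,auct->asct", Lg, b["z_gamma"])
        gamma = sigma_g[:, None, None, None] * Lgz
        return ModelParams(
            mu_beta=b["mu_beta"].copy(),
            omega=omega,
            sigma_beta=sigma_b.copy(),
            L_beta=Lb[:, :, :, :].copy(),
            sigma_mu=np.exp(b["lsm"]),
            gamma=gamma,
            sigma_gamma=sigma_g,
            L_gamma=Lg[:, :, :, :].copy(),
        )

    def log_lambda(self, theta: np.ndarray) -> np.ndarray:
        p = self.constrain(theta)
        return np.einsum("ai,isct->asct", self.Y, p.beta) + p.gamma

    # -- density and gradient ---------------------------------------------
    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.config
        b = self.unpack(theta)
        mu_beta, lsm = b["mu_beta"], b["lsm"]
        z_omega, lsb = b["z_omega"], b["lsb"]
        z_gamma, lsg = b["z_gamma"], b["lsg"]
        y_Lb = b.get("y_Lb")
        y_Lg = b.get("y_Lg")

        P, S, C, T, A = self.P, self.S, self.C, self.T, self.A

        if self.identity_corr:
            Lb, Lg = self._eye_b, self._eye_g
            Lb_small = Lg_small = None
        else:
            Lb_small = cpc_to_cholesky(y_Lb.reshape(-1, self.M), S)
            Lb = Lb_small.reshape(P, self.Tb, S, S)
            if self.Tb == 1:
                Lb = np.broadcast_to(Lb, (P, T, S, S))
            Lg_small = cpc_to_cholesky(y_Lg.reshape(-1, self.M), S)
            Lg = Lg_small.reshape(A, self.Tg, S, S)
            if self.Tg == 1:
                Lg = np.broadcast_to(Lg, (A, T, S, S))
        sigma_b = np.exp(lsb)
        sb_full = (
            np.broadcast_to(sigma_b, (P, S, T)) if self.Sb == 1 else sigma_b
        )
        sigma_g = np.exp(lsg)
        sigma_m = np.exp(lsm)

        Lz = np.einsum("ptsu,puct->psct", Lb, z_omega)
        omega = sb_full[:, :, None, :] * Lz
        beta = mu_beta[:, :, None, :] + omega
        Lgz = np.einsum("atsu,auct->asct", Lg, z_gamma)
        gamma = sigma_g[:, None, None, None] * Lgz
        loglam = np.einsum("ai,isct->asct", self.Y, beta) + gamma

        with np.errstate(over="ignore"):
            # exp only where the cell is in the likelihood, so masked cells
            # can never poison the density with 0 * inf
            mu_pois = self._em * np.exp(np.where(self._mask, loglam, 0.0))
        if not np.all(np.isfinite(mu_pois)):
            return -np.inf, np.zeros_like(theta)

        logp = float(np.sum(self._ym * loglam - mu_pois))

        # priors on innovations
        logp += -0.5 * float(np.sum(z_omega**2)) - 0.5 * float(np.sum(z_gamma**2))
        # half-normal scales (log-scale sampling: Jacobian + log sigma)
        hb = cfg.sigma_beta_scale
        hg = cfg.sigma_gamma_scale
        logp += float(np.sum(-0.5 * (sigma_b / hb) ** 2 + lsb))
        logp += float(np.sum(-0.5 * (sigma_g / hg) ** 2 + lsg))
        # log-normal on sigma_mu: normal on lsm (Jacobian cancels the 1/sigma)
        sm_scale = cfg.sigma_mu_logscale
        logp += float(np.sum(-0.5 * ((lsm - cfg.sigma_mu_logloc) / sm_scale) ** 2))
        # RW2 on mu_beta, flat first two points
        if T >= 3:
            r = mu_beta[:, :, 2:] - 2.0 * mu_beta[:, :, 1:-1] + mu_beta[:, :, :-2]
            inv_v = 1.0 / sigma_m**2  # (P,)
            logp += float(
                np.sum(-0.5 * r**2 * inv_v[:, None, None])
                - S * (T - 2) * np.sum(lsm)
            )
        else:
            r = None
        # LKJ priors
        if not self.identity_corr:
            logp += lkj_logdensity(y_Lb, S, cfg.lkj_eta)
            logp += lkj_logdensity(y_Lg, S, cfg.lkj_eta)

        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(theta)

        # ---- gradient ----
        D = self._ym - mu_pois  # (A,S,C,T), zero where masked out
        g = {}
        g["z_gamma"] = (
            np.einsum("atsu,asct->auct", Lg, D) * sigma_g[:, None, None, None]
            - z_gamma
        )
        g["lsg"] = (
            np.einsum("asct,asct->a", D, Lgz) * sigma_g
            - (sigma_g / hg) ** 2
            + 1.0
        )
        dbeta = np.einsum("ai,asct->isct", self.Y, D)
        g["mu_beta"] = dbeta.sum(axis=2)
        if r is not None:
            rr = r * (1.0 / sigma_m**2)[:, None, None]
            g["mu_beta"][:, :, 2:] -= rr
            g["mu_beta"][:, :, 1:-1] += 2.0 * rr
            g["mu_beta"][:, :, :-2] -= rr
            g["lsm"] = (
                np.sum(r**2, axis=(1, 2)) / sigma_m**2 - S * (T - 2)
            )
        else:
            g["lsm"] = np.zeros(P)
        g["lsm"] += -(lsm - cfg.sigma_mu_logloc) / sm_scale**2

        dLz = dbeta * sb_full[:, :, None, :]
        g["z_omega"] = np.einsum("ptsu,psct->puct", Lb, dLz) - z_omega
        dsb_full = np.einsum("isct,isct->ist", dbeta, Lz) * sb_full
        if self.Sb == 1:
            dlsb = dsb_full.sum(axis=1, keepdims=True)
        else:
            dlsb = dsb_full
        g["lsb"] = dlsb - (sigma_b / hb) ** 2 + 1.0

        if not self.identity_corr:
            tril = self._tril
            dLb = np.einsum("psct,puct->ptsu", dLz, z_omega) * tril
            if self.Tb == 1:
                dLb = dLb.sum(axis=1, keepdims=True)
            g["y_Lb"] = cholesky_backward(
                y_Lb.reshape(-1, self.M), dLb.reshape(-1, S, S), S, L=Lb_small
            ).reshape(y_Lb.shape) + lkj_grad(y_Lb, S, cfg.lkj_eta)
            dLgz_full = D * sigma_g[:, None, None, None]
            dLg = np.einsum("asct,auct->atsu", dLgz_full, z_gamma) * tril
            if self.Tg == 1:
                dLg = dLg.sum(axis=1, keepdims=True)
            g["y_Lg"] = cholesky_backward(
                y_Lg.reshape(-1, self.M), dLg.reshape(-1, S, S), S, L=Lg_small
            ).reshape(y_Lg.shape) + lkj_grad(y_Lg, S, cfg.lkj_eta)

        grad = self.pack(g)
        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # -- initialization ----------------------------------------------------
    def initial_theta(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Data-informed starting point with per-chain jitter.

        Group-level means start at the least-squares projection of pooled
        crude log rates onto the basis; all innovations start near zero and
        scales near their prior medians.
        """
        P, S, T, A = self.P, self.S, self.T, self.A
        mu0 = np.zeros((P, S, T))
        for s in range(S):
            for t in range(T):
                y = self._ym[:, s, :, t].sum(axis=1)
                e = self._em[:, s, :, t].sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    crude = np.log((y + 0.5) / np.maximum(e, 1.0))
                ok = e > 0
                if ok.sum() >= P:
                    coef, *_ = np.linalg.lstsq(self.Y[ok], crude[ok], rcond=None)
                    mu0[:, s, t] = coef
        blocks = {
            "mu_beta": mu0 + jitter * rng.standard_normal((P, S, T)),
            "lsm": np.full(P, self.config.sigma_mu_logloc)
            + jitter * rng.standard_normal(P),
            "z_omega": jitter * rng.standard_normal((P, S, self.C, T)),
            "lsb": np.log(0.1) + jitter * rng.standard_normal((P, self.Sb, T)),
            "z_gamma": jitter * rng.standard_normal((A, S, self.C, T)),
            "lsg": np.log(0.05) + jitter * rng.standard_normal(A),
        }
        if not self.identity_corr:
            blocks["y_Lb"] = jitter * rng.standard_normal((P, self.Tb, self.M))
            blocks["y_Lg"] = jitter * rng.standard_normal((A, self.Tg, self.M))
        return self.pack(blocks)
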