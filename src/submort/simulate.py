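"""Synthetic multi-area, multi-subpopulation mortality datasets with known truth.

The generator mirrors the model's own structure: each cell's true log
mortality rate is a linear combination of two standard age schedules — a
J-shaped baseline and a young-adult "accident hump" — with subpopulation
coefficients drawn multivariate normal around subpopulation means under
known cross-subpopulation correlation matrices.  Deaths are Poisson with
mean exposure times rate.  Because the generating coefficients and
correlations are returned alongside the data, recovery experiments can score
posterior credible intervals against exact truth.

Default dimensions follow the recovery-study design: 25 areas observed for
10 years, 5 subpopulations with population shares from 10% to 50%, area
populations log-uniform between 10^4 and 10^6 so that per-cell expected
deaths range from near zero in small areas to hundreds in large ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .basis import PCBasis
from .data import MortalityDataset

DEFAULT_SHARES = (0.10, 0.10, 0.15, 0.15, 0.50)


def default_true_corr(n_subpops: int) -> np.ndarray:
    """Generating correlation matrices for the two coefficient vectors.

    Coefficient 1 (baseline level): strong exchangeable correlation (0.9) —
    when general conditions in an area change, every group moves together.
    Coefficient 2 (accident hump): two internally cohesive blocks (0.8) with
    mild negative cross-block correlation (-0.3), a pattern with both high
    and low entries and an exact sign structure for recovery checks.
    """
    S = n_subpops
    c1 = np.full((S, S), 0.9)
    np.fill_diagonal(c1, 1.0)
    c2 = np.full((S, S), -0.3)
    k = (S + 1) // 2
    c2[:k, :k] = 0.8
    c2[k:, k:] = 0.8
    np.fill_diagonal(c2, 1.0)
    out = np.stack([c1, c2])
    for m in out:
        if np.linalg.eigvalsh(m).min() <= 1e-10:
            raise ValueError("default correlation construction is not PD")
    return out


@dataclass
class SimulationConfig:
    """Generating process for the recovery study; defaults are the study design."""

    n_areas: int = 25
    n_years: int = 10
    n_subpops: int = 5
    n_ages: int = 10
    subpop_shares: Sequence[float] | None = None
    pop_min: float = 5e4
    pop_max: float = 5e6
    coef_means: np.ndarray | None = None   # (2, S)
    coef_scales: Sequence[float] = (0.10, 0.35)
    true_corr: np.ndarray | None = None    # (2, S, S)
    seed: int = 0

    def __post_init__(self) -> None:
        S = self.n_subpops
        if self.subpop_shares is None:
            if S == 5:
                self.subpop_shares = np.array(DEFAULT_SHARES)
            else:
                w = np.linspace(1.0, 3.0, S)
                self.subpop_shares = w / w.sum()
        self.subpop_shares = np.asarray(self.subpop_shares, dtype=float)
        if len(self.subpop_shares) != S:
            raise ValueError("one share per subpopulation required")
        if np.any(self.subpop_shares <= 0) or np.any(self.subpop_shares >= 1):
            raise ValueError("shares must lie in (0, 1)")
        if not np.isclose(self.subpop_shares.sum(), 1.0):
            raise ValueError("shares must sum to 1")
        if self.coef_means is None:
            # group gradient: higher baseline coefficient = lower mortality
            # (the J curve is negative); hump loading rises across groups
            self.coef_means = np.stack(
                [np.linspace(0.92, 1.08, S), np.linspace(0.10, 0.50, S)]
            )
        self.coef_means = np.asarray(self.coef_means, dtype=float)
        if self.true_corr is None:
            self.true_corr = default_true_corr(S)
        self.true_corr = np.asarray(self.true_corr, dtype=float)
        for m in self.true_corr:
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("true correlation matrices need unit diagonal")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError("true correlation matrix is not positive definite")
        if self.n_ages < 3:
            raise ValueError("need at least 3 age groups")


@dataclass
class SimulationTruth:
    """Everything the generator knew: coefficients, rates, correlations."""

    coefficients: np.ndarray   # (2, S, C, T)
    log_rates: np.ndarray      # (A, S, C, T)
    true_corr: np.ndarray      # (2, S, S)
    curves: np.ndarray         # (A, 2)
    area_populations: np.ndarray  # (C,)


def make_standard_curves(n_ages: int, seed: int = 0) -> np.ndarray:
    """Two deterministic standard log-mortality age schedules, (A, 2).

    Curve 1 is the J-shaped baseline: elevated infant mortality, a childhood
    minimum near exp(-8.2), then a log-linear (Gompertz-like) rise to the
    oldest group; all entries negative and strictly increasing beyond the
    minimum.  Curve 2 is a unit-peak young-adult hump (Gaussian bump in age).
    A seed adds a small smooth perturbation so distinct seeds give distinct
    but equally shaped curves; the same (A, seed) always returns identical
    values.
    """
    A = n_ages
    if A < 3:
        raise ValueError("need at least 3 age groups")
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, A)
    i_min = max(1, A // 6)
    curve1 = np.empty(A)
    curve1[0] = -4.2
    curve1[i_min] = -8.2
    if i_min > 1:
        curve1[1:i_min] = np.linspace(-4.2, -8.2, i_min + 1)[1:-1]
    curve1[i_min:] = np.linspace(-8.2, -1.8, A - i_min)
    # smooth, small, monotonicity-preserving noise (step size is ~0.8)
    bumps = rng.normal(0.0, 0.05, A)
    curve1 = curve1 + np.convolve(bumps, np.ones(3) / 3, mode="same")
    curve2 = np.exp(-0.5 * ((u - 0.22) / 0.13) ** 2)
    curve2 = curve2 / curve2.max()
    curve2 = np.clip(curve2 + rng.normal(0.0, 0.01, A), 0.0, None)
    return np.column_stack([curve1, curve2])


def basis_from_curves(curves: np.ndarray) -> PCBasis:
    """Wrap standard curves as a basis usable by the model (columns as given)."""
    curves = np.asarray(curves, dtype=float)
    return PCBasis(
        components=curves,
        singular_values=np.ones(curves.shape[1]),
        left_values=np.eye(curves.shape[1]),
        age_groups=[f"age_{i}" for i in range(curves.shape[0])],
    )


def draw_coefficients(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Correlated subpopulation coefficients, one S-vector per (curve, area, year).

    b_k[., c, t] ~ MVN(coef_means[k], coef_scales[k]^2 * true_corr[k]), drawn
    independently over areas and years, so the empirical cross-subpopulation
    correlation converges to true_corr as C*T grows.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    S, C, T = cfg.n_subpops, cfg.n_areas, cfg.n_years
    out = np.empty((2, S, C, T))
    for k in range(2):
        L = np.linalg.cholesky(cfg.true_corr[k])
        z = rng.standard_normal((S, C * T))
        draws = cfg.coef_means[k][:, None] + cfg.coef_scales[k] * (L @ z)
        out[k] = draws.reshape(S, C, T)
    return out


def _age_weights(n_ages: int) -> np.ndarray:
    # mildly declining population pyramid over age groups
    w = np.exp(-0.8 * np.linspace(0.0, 1.0, n_ages))
    return w / w.sum()


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[MortalityDataset, SimulationTruth]:
    """Draw a full synthetic dataset plus its generating truth."""
    rng = np.random.default_rng(cfg.seed)
    A, S, C, T = cfg.n_ages, cfg.n_subpops, cfg.n_areas, cfg.n_years
    curves = make_standard_curves(A, cfg.seed)
    coefs = draw_coefficients(cfg, rng)
    log_rates = np.einsum("ak,ksct->asct", curves, coefs)
    pops = np.exp(
        rng.uniform(np.log(cfg.pop_min), np.log(cfg.pop_max), size=C)
    )
    w = _age_weights(A)
    exposures = (
        w[:, None, None, None]
        * cfg.subpop_shares[None, :, None, None]
        * pops[None, None, :, None]
        * np.ones((1, 1, 1, T))
    )
    means = exposures * np.exp(log_rates)
    if np.any(means > 1e9):
        raise ValueError("expected deaths exceed 1e9 in some cell; check config")
    deaths = rng.poisson(means)
    dataset = MortalityDataset(
        deaths=deaths,
        exposures=exposures,
        ages=[f"age_{i}" for i in range(A)],
        subpops=[f"group_{i + 1}" for i in range(S)],
        areas=[f"area_{i + 1:02d}" for i in range(C)],
        years=list(range(2000, 2000 + T)),
    )
    truth = SimulationTruth(
        coefficients=coefs,
        log_rates=log_rates,
        true_corr=cfg.true_corr.copy(),
        curves=curves,
        area_populations=pops,
    )
    return dataset, truth
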