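"""Validation metrics: interval coverage, hold-out splits, predictive scoring.

Two validation modes are supported.  Against synthetic data with known
truth, entrywise credible-interval coverage is computed for correlation
matrices and log mortality rates — for a calibrated model the fraction of
truths inside level-q intervals is close to q.  Against real (or held-out
synthetic) data, a fraction of observed death counts is masked per area, the
model is refit, and posterior-predictive death distributions for the masked
cells are scored by interval coverage, mean absolute deviation (MAD) and
mean squared error (MSE) of the predictive medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MortalityDataset
from .inference import PosteriorSamples
from .simulate import SimulationTruth

DEFAULT_LEVELS = (0.80, 0.90, 0.95)


def interval_coverage(
    truths: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> float:
    """Fraction of truths inside their closed intervals: mean 1{l <= x <= u}."""
    truths = np.asarray(truths, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (truths.shape == lower.shape == upper.shape):
        raise ValueError("truths, lower and upper must have equal shapes")
    if np.any(lower > upper):
        raise ValueError("interval bounds are crossed (lower > upper)")
    return float(np.mean((lower <= truths) & (truths <= upper)))


def _tail(level: float) -> tuple[float, float]:
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    t = (1 - level) / 2
    return t, 1 - t


def correlation_coverage(
    samples: PosteriorSamples,
    truth: SimulationTruth,
    level: float,
    kind: str = "beta",
) -> tuple[float, int]:
    """Entrywise coverage over lower-triangle off-diagonals of all correlation
    matrices at one nominal level; returns (coverage, n entries).

    The generating correlations are time-constant; each sampled matrix
    (per component and year) is scored against the matching truth entry.
    """
    key = {"beta": "corr_beta", "gamma": "corr_gamma"}[kind]
    draws = samples.stacked(key)  # (n, K, T, S, S)
    _, K, T, S, _ = draws.shape
    lo_q, hi_q = _tail(level)
    il, jl = np.tril_indices(S, k=-1)
    tru, lo, hi = [], [], []
    for k in range(K):
        truth_k = truth.true_corr[min(k, truth.true_corr.shape[0] - 1)]
        for t in range(T):
            vals = draws[:, k, t][:, il, jl]  # (n, M)
            tru.append(truth_k[il, jl])
            lo.append(np.quantile(vals, lo_q, axis=0))
            hi.append(np.quantile(vals, hi_q, axis=0))
    tru, lo, hi = map(np.concatenate, (tru, lo, hi))
    return interval_coverage(tru, lo, hi), tru.size


def lograte_coverage(
    samples: PosteriorSamples, truth: SimulationTruth, level: float
) -> tuple[float, int]:
    """Entrywise coverage of true log rates by posterior intervals."""
    draws = samples.stacked("log_lambda")  # (n, A, S, C, T)
    lo_q, hi_q = _tail(level)
    lo = np.quantile(draws, lo_q, axis=0)
    hi = np.quantile(draws, hi_q, axis=0)
    return (
        interval_coverage(truth.log_rates.ravel(), lo.ravel(), hi.ravel()),
        truth.log_rates.size,
    )


@dataclass
class CoverageReport:
    """Coverage fractions by nominal level for correlations and log rates."""

    levels: tuple[float, ...]
    correlation_coverage: dict[float, float]
    lograte_coverage: dict[float, float]
    n_correlation: int
    n_lograte: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "correlations": [self.correlation_coverage[q] for q in self.levels],
                "log_rates": [self.lograte_coverage[q] for q in self.levels],
            }
        )


def coverage_report(
    samples: PosteriorSamples,
    truth: SimulationTruth,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> CoverageReport:
    corr_cov, lr_cov = {}, {}
    n_corr = n_lr = 0
    for q in levels:
        corr_cov[q], n_corr = correlation_coverage(samples, truth, q)
        lr_cov[q], n_lr = lograte_coverage(samples, truth, q)
    return CoverageReport(
        levels=tuple(levels),
        correlation_coverage=corr_cov,
        lograte_coverage=lr_cov,
        n_correlation=n_corr,
        n_lograte=n_lr,
    )


def holdout_split(
    data: MortalityDataset, fraction: float = 0.20, seed: int = 0
) -> tuple[MortalityDataset, pd.DataFrame]:
    """Mask a fraction of each area's observed death counts out of the likelihood.

    Per area, ``round(fraction * n_observed)`` cells are drawn uniformly at
    random from the cells currently in the likelihood and masked; exposures
    stay observed (they come from a census-type source, not death
    registration).  Returns the masked dataset and a frame listing the
    held-out cells with their observed counts.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    in_sample = data.copy()
    rows = []
    A, S, C, T = data.shape
    for c in range(C):
        obs = np.argwhere(data.mask[:, :, c, :])  # (n_obs, 3): a, s, t
        n_obs = len(obs)
        if n_obs == 0:
            continue
        n_hold = min(int(round(fraction * n_obs)), n_obs - 1)
        if n_hold == 0:
            continue
        pick = rng.choice(n_obs, size=n_hold, replace=False)
        for a, s, t in obs[pick]:
            in_sample.mask[a, s, c, t] = False
            rows.append(
                {
                    "age_idx": int(a), "subpop_idx": int(s),
                    "area_idx": int(c), "year_idx": int(t),
                    "age_group": data.ages[a],
                    "subpopulation": data.subpops[s],
                    "area": data.areas[c],
                    "year": data.years[t],
                    "deaths": int(data.deaths[a, s, c, t]),
                    "exposure": float(data.exposures[a, s, c, t]),
                }
            )
    return in_sample, pd.DataFrame(rows)


def posterior_predictive_deaths(
    samples: PosteriorSamples,
    cells: pd.DataFrame,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive death-count summaries for held-out cells.

    For each posterior draw of the cell's rate, one Poisson count is drawn
    with mean exposure * rate; the predictive median and equal-tailed
    quantile intervals (integer-valued endpoints) are reported per cell.
    """
    rng = np.random.default_rng(seed)
    loglam = samples.stacked("log_lambda")  # (n, A, S, C, T)
    a = cells["age_idx"].to_numpy()
    s = cells["subpop_idx"].to_numpy()
    c = cells["area_idx"].to_numpy()
    t = cells["year_idx"].to_numpy()
    expo = cells["exposure"].to_numpy()
    lam = np.exp(loglam[:, a, s, c, t])  # (n_draws, n_cells)
    pred = rng.poisson(expo[None, :] * lam)
    out = cells.copy()
    out["pred_median"] = np.median(pred, axis=0)
    for q in levels:
        lo_q, hi_q = _tail(q)
        pct = int(round(q * 100))
        out[f"pred_lower_{pct}"] = np.quantile(pred, lo_q, axis=0)
        out[f"pred_upper_{pct}"] = np.quantile(pred, hi_q, axis=0)
    return out


@dataclass
class HoldoutReport:
    """Predictive-interval coverage and point-error metrics on held-out counts."""

    coverage: dict[float, float]
    mad: float
    mse: float
    n_cells: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"coverage_{int(round(q * 100))}", "value": v}
            for q, v in self.coverage.items()
        ]
        rows += [
            {"metric": "mad", "value": self.mad},
            {"metric": "mse", "value": self.mse},
            {"metric": "n_cells", "value": self.n_cells},
        ]
        return pd.DataFrame(rows)


def holdout_metrics(
    predictive: pd.DataFrame,
    observed: np.ndarray | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int | None = None,
) -> HoldoutReport:
    """Score predictive summaries against observed held-out counts.

    MAD and MSE compare predictive medians to observations; coverage counts
    an observation equal to an interval bound as covered (closed intervals).
    """
    y = (
        predictive["deaths"].to_numpy()
        if observed is None
        else np.asarray(observed, dtype=float)
    )
    med = predictive["pred_median"].to_numpy(dtype=float)
    if len(y) != len(med):
        raise ValueError("observed and predictive lengths differ")
    cov = {}
    for q in levels:
        pct = int(round(q * 100))
        cov[q] = interval_coverage(
            y,
            predictive[f"pred_lower_{pct}"].to_numpy(dtype=float),
            predictive[f"pred_upper_{pct}"].to_numpy(dtype=float),
        )
    err = med - y
    return HoldoutReport(
        coverage=cov,
        mad=float(np.mean(np.abs(err))),
        mse=float(np.mean(err**2)),
        n_cells=len(y),
        seed=seed,
    )
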