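"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of the dynamic Hamiltonian Monte Carlo
algorithm of Hoffman & Gelman (2014, Algorithm 6: slice-sampled tree
doubling with the no-U-turn termination criterion), with Stan-style warmup:
an initial step-size phase, expanding memoryless windows estimating a
diagonal metric from the warmup draws, and a terminal step-size phase.

The target is supplied as a callable ``logp_grad(theta) -> (logp, grad)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NUTSResult"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the energy error


@dataclass
class NUTSResult:
    samples: np.ndarray          # (n_samples, dim) post-warmup draws
    logp: np.ndarray             # (n_samples,) log density of each draw
    n_divergent: int
    treedepths: np.ndarray       # (n_samples,)
    step_size: float
    inv_mass: np.ndarray
    accept_stat: float           # mean Metropolis acceptance statistic


class _Tree:
    """State carried while recursively doubling a trajectory."""

    __slots__ = (
        "minus_q", "minus_p", "minus_g", "plus_q", "plus_p", "plus_g",
        "proposal_q", "proposal_logp", "proposal_g", "n_valid", "keep_going",
        "sum_alpha", "n_alpha", "divergent",
    )


def _leapfrog(logp_grad, q, p, g, eps, inv_mass):
    p = p + 0.5 * eps * g
    q = q + eps * inv_mass * p
    logp, g = logp_grad(q)
    p = p + 0.5 * eps * g
    return q, p, g, logp


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _find_reasonable_epsilon(logp_grad, q0, rng, inv_mass):
    eps = 1.0
    logp0, g0 = logp_grad(q0)
    p0 = rng.standard_normal(q0.shape) / np.sqrt(inv_mass)
    h0 = logp0 - _kinetic(p0, inv_mass)
    q, p, g, logp = _leapfrog(logp_grad, q0, p0, g0, eps, inv_mass)
    h = logp - _kinetic(p, inv_mass)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q, p, g, logp = _leapfrog(logp_grad, q0, p0, g0, eps, inv_mass)
        h = logp - _kinetic(p, inv_mass)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) < direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, q, p, g, log_u, direction, depth, eps, h0, inv_mass, rng):
    if depth == 0:
        q1, p1, g1, logp1 = _leapfrog(logp_grad, q, p, g, direction * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        t = _Tree()
        t.minus_q, t.minus_p, t.minus_g = q1, p1, g1
        t.plus_q, t.plus_p, t.plus_g = q1, p1, g1
        t.proposal_q, t.proposal_logp, t.proposal_g = q1, logp1, g1
        t.n_valid = 1 if log_u <= h1 else 0
        t.divergent = log_u - _MAX_ENERGY_ERROR > h1
        t.keep_going = not t.divergent
        t.sum_alpha = float(np.exp(min(0.0, h1 - h0)))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, q, p, g, log_u, direction, depth - 1, eps, h0,
                    inv_mass, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.minus_q, t.minus_p, t.minus_g, log_u,
                             direction, depth - 1, eps, h0, inv_mass, rng)
            t.minus_q, t.minus_p, t.minus_g = t2.minus_q, t2.minus_p, t2.minus_g
        else:
            t2 = _build_tree(logp_grad, t.plus_q, t.plus_p, t.plus_g, log_u,
                             direction, depth - 1, eps, h0, inv_mass, rng)
            t.plus_q, t.plus_p, t.plus_g = t2.plus_q, t2.plus_p, t2.plus_g
        total = t.n_valid + t2.n_valid
        if t2.n_valid > 0 and rng.uniform() < t2.n_valid / total:
            t.proposal_q, t.proposal_logp, t.proposal_g = (
                t2.proposal_q, t2.proposal_logp, t2.proposal_g)
        t.n_valid = total
        dq = t.plus_q - t.minus_q
        t.keep_going = (
            t2.keep_going
            and not t2.divergent
            and np.dot(dq, inv_mass * t.minus_p) >= 0
            and np.dot(dq, inv_mass * t.plus_p) >= 0
        )
        t.divergent = t.divergent or t2.divergent
        t.sum_alpha += t2.sum_alpha
        t.n_alpha += t2.n_alpha
    return t


def _mass_windows(n_warmup: int):
    """Stan-style warmup schedule: (init, windows..., term) iteration spans."""
    init, term, base = 75, 50, 25
    if n_warmup < 20:
        return n_warmup, [], 0
    if n_warmup < init + term + base:
        init_ = max(1, int(0.15 * n_warmup))
        term_ = max(1, int(0.10 * n_warmup))
        return init_, [n_warmup - init_ - term_], term_
    windows = []
    left = n_warmup - init - term
    w = base
    while left > 0:
        if left < 2 * w:
            w = left
        windows.append(min(w, left))
        left -= min(w, left)
        w *= 2
    return init, windows, term


def nuts_sample(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    seed: int | np.random.Generator,
    adapt_delta: float = 0.95,
    max_treedepth: int = 10,
) -> NUTSResult:
    """Run one NUTS chain and return post-warmup draws."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = np.array(theta0, dtype=float)
    dim = q.size
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(logp_grad, q, rng, inv_mass)
    # dual averaging state; m_da counts iterations since the last restart
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_da = 0.0, 0.0, 0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    init_w, windows, term_w = _mass_windows(n_warmup)
    window_bounds = []
    start = init_w
    for w in windows:
        window_bounds.append((start, start + w))
        start += w

    samples = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    depths = np.empty(n_samples, dtype=int)
    n_div = 0
    sum_accept, n_accept = 0.0, 0

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    win_idx = 0

    logp, g = logp_grad(q)
    total_iters = n_warmup + n_samples
    for it in range(total_iters):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(p0, inv_mass)
        log_u = h0 + np.log(rng.uniform())
        t = _Tree()
        t.minus_q, t.minus_p, t.minus_g = q, p0, g
        t.plus_q, t.plus_p, t.plus_g = q, p0, g
        t.proposal_q, t.proposal_logp, t.proposal_g = q, logp, g
        t.n_valid, t.keep_going, t.divergent = 1, True, False
        depth = 0
        accept_prob, n_alpha = 0.0, 0
        while t.keep_going and depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == -1:
                sub = _build_tree(logp_grad, t.minus_q, t.minus_p, t.minus_g,
                                  log_u, -1, depth, eps, h0, inv_mass, rng)
                t.minus_q, t.minus_p, t.minus_g = sub.minus_q, sub.minus_p, sub.minus_g
            else:
                sub = _build_tree(logp_grad, t.plus_q, t.plus_p, t.plus_g,
                                  log_u, 1, depth, eps, h0, inv_mass, rng)
                t.plus_q, t.plus_p, t.plus_g = sub.plus_q, sub.plus_p, sub.plus_g
            if sub.keep_going and sub.n_valid > 0:
                if rng.uniform() < sub.n_valid / max(t.n_valid, 1):
                    t.proposal_q, t.proposal_logp, t.proposal_g = (
                        sub.proposal_q, sub.proposal_logp, sub.proposal_g)
            t.n_valid += sub.n_valid
            accept_prob += sub.sum_alpha
            n_alpha += sub.n_alpha
            dq = t.plus_q - t.minus_q
            t.keep_going = (
                sub.keep_going
                and not sub.divergent
                and np.dot(dq, inv_mass * t.minus_p) >= 0
                and np.dot(dq, inv_mass * t.plus_p) >= 0
            )
            if sub.divergent:
                if not warming:
                    n_div += 1
                break
            depth += 1
        q, logp, g = t.proposal_q, t.proposal_logp, t.proposal_g
        alpha_stat = accept_prob / max(n_alpha, 1)

        if warming:
            # dual averaging
            m_da += 1
            eta = 1.0 / (m_da + t0_da)
            h_bar = (1 - eta) * h_bar + eta * (adapt_delta - alpha_stat)
            log_eps = mu_da - np.sqrt(m_da) / gamma_da * h_bar
            pw = m_da**-kappa_da
            log_eps_bar = pw * log_eps + (1 - pw) * log_eps_bar
            eps = float(np.exp(log_eps))
            # mass-matrix window accumulation
            if win_idx < len(window_bounds):
                lo, hi = window_bounds[win_idx]
                if lo <= it < hi:
                    welford_n += 1
                    delta = q - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (q - welford_mean)
                if it == hi - 1:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        # regularize as Stan does
                        var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                            5.0 / (welford_n + 5.0)
                        )
                        inv_mass = var
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    # metric changed: re-tune the step size from scratch
                    eps = _find_reasonable_epsilon(logp_grad, q, rng, inv_mass)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar, m_da = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - n_warmup
            samples[i] = q
            logps[i] = logp
            depths[i] = depth
            sum_accept += alpha_stat
            n_accept += 1

    return NUTSResult(
        samples=samples,
        logp=logps,
        n_divergent=n_div,
        treedepths=depths,
        step_size=eps,
        inv_mass=inv_mass,
        accept_stat=sum_accept / max(n_accept, 1),
    )
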