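"""Unconstrained parameterization of correlation-matrix Cholesky factors.

A correlation matrix R = L L' with L lower-triangular and unit-norm rows is
parameterized by S(S-1)/2 canonical partial correlations (CPCs) z in (-1, 1),
themselves the tanh image of an unconstrained vector y.  The construction is
the C-vine of Lewandowski, Kurowicka & Joe: under independent scaled-Beta
distributions on the CPCs the matrix is LKJ(eta) distributed, which gives a
closed-form log density (and gradient) for the LKJ prior directly in y-space.

All functions are vectorized over an arbitrary batch of matrices sharing S.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def n_cpc(S: int) -> int:
    """Number of free parameters for an S x S correlation matrix."""
    return S * (S - 1) // 2


@lru_cache(maxsize=None)
def _tril_indices(S: int) -> tuple[np.ndarray, np.ndarray]:
    # strict lower triangle, row-major: (1,0), (2,0), (2,1), (3,0), ...
    return np.tril_indices(S, k=-1)


@lru_cache(maxsize=None)
def _cached_exponents(S: int, eta: float) -> np.ndarray:
    _, cols = _tril_indices(S)
    return eta + (S - 2 - cols) / 2.0


def cpc_to_cholesky(y: np.ndarray, S: int) -> np.ndarray:
    """Map unconstrained CPC vectors to Cholesky factors of correlation matrices.

    Parameters
    ----------
    y : array, shape (..., S*(S-1)/2)
        Unconstrained parameters; z = tanh(y) are the partial correlations.
    S : int
        Matrix dimension.

    Returns
    -------
    L : array, shape (..., S, S)
        Lower-triangular with unit-norm rows, so that L @ L.T is a
        correlation matrix.
    """
    y = np.asarray(y, dtype=float)
    z = np.tanh(y)
    batch = y.shape[:-1]
    L = np.zeros(batch + (S, S))
    L[..., 0, 0] = 1.0
    idx = 0
    for i in range(1, S):
        w = np.ones(batch)
        for j in range(i):
            zij = z[..., idx]
            L[..., i, j] = zij * w
            w = w * np.sqrt(1.0 - zij**2)
            idx += 1
        L[..., i, i] = w
    return L

def cholesky_backward(
    y: np.ndarray, dL: np.ndarray, S: int, L: np.ndarray | None = None
) -> np.ndarray:
    """Backpropagate a gradient w.r.t. L through ``cpc_to_cholesky``.

    Given dlogp/dL (including the diagonal, which is a deterministic function
    of the CPCs), returns dlogp/dy.  Pass the forward result ``L`` to avoid
    recomputing it.
    """
    y = np.asarray(y, dtype=float)
    z = np.tanh(y)
    batch = y.shape[:-1]
    if L is None:
        L = cpc_to_cholesky(y, S)
    dy = np.zeros_like(y)
    idx = 0
    row_start = {}
    for i in range(1, S):
        row_start[i] = idx
        idx += i
    for i in range(1, S):
        base = row_start[i]
        # suffix sums s_k = sum_{j>k} dL[i,j] * L[i,j]  (j up to and incl. diagonal)
        s = dL[..., i, i] * L[..., i, i]
        for k in range(i - 1, -1, -1):
            zk = z[..., base + k]
            # prefix product w_k = prod_{m<k} sqrt(1 - z_m^2)
            if k == 0:
                wk = np.ones(batch)
            else:
                wk = np.prod(
                    np.sqrt(1.0 - z[..., base : base + k] ** 2), axis=-1
                )
            one_m_zk2 = np.maximum(1.0 - zk**2, 1e-300)  # tanh saturation guard
            dz = dL[..., i, k] * wk - zk / one_m_zk2 * s
            dy[..., base + k] = dz * (1.0 - zk**2)
            s = s + dL[..., i, k] * L[..., i, k]
    return dy


def _lkj_exponents(S: int, eta: float) -> np.ndarray:
    """Per-CPC exponents c s.t. the y-space LKJ log density is sum c*log(1-z^2).

    For the CPC in (strict lower triangle) column k (0-indexed) the exponent is
    eta + (S - 2 - k) / 2; this includes the tanh Jacobian, so that for S = 2,
    eta = 1 the implied correlation is uniform on (-1, 1).
    """
    return _cached_exponents(S, float(eta))


def lkj_logdensity(y: np.ndarray, S: int, eta: float = 1.0) -> float:
    """LKJ(eta) log density in unconstrained y-space (tanh Jacobian included).

    Unnormalized; summed over every matrix in the batch.
    """
    y = np.asarray(y, dtype=float)
    c = _lkj_exponents(S, eta)
    # log(1 - tanh(y)^2) = 2*(log 2 - |y| - log1p(exp(-2|y|))), stable for large |y|
    a = np.abs(y)
    log1mz2 = 2.0 * (np.log(2.0) - a - np.log1p(np.exp(-2.0 * a)))
    return float(np.sum(c * log1mz2))


def lkj_grad(y: np.ndarray, S: int, eta: float = 1.0) -> np.ndarray:
    """Gradient of :func:`lkj_logdensity` w.r.t. y."""
    y = np.asarray(y, dtype=float)
    c = _lkj_exponents(S, eta)
    return -2.0 * c * np.tanh(y)


def sample_lkj_cpc(S: int, eta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw CPC vectors whose induced correlation matrices are LKJ(eta).

    Each CPC in column k is distributed as 2*Beta(a, a) - 1 with
    a = eta + (S - 2 - k)/2 (C-vine construction); used as an independent
    sampling route for prior checks.
    """
    a = _cached_exponents(S, float(eta))
    z = 2.0 * rng.beta(a, a, size=(size, len(a))) - 1.0
    return z


def correlation_from_cpc_z(z: np.ndarray, S: int) -> np.ndarray:
    """Correlation matrices from raw CPC values z in (-1,1) (batched)."""
    y = np.arctanh(np.clip(z, -1 + 1e-12, 1 - 1e-12))
    L = cpc_to_cholesky(y, S)
    return L @ np.swapaxes(L, -1, -2)
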