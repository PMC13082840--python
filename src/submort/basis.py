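"""Principal-component age schedules from a reference log-mortality matrix.

Mortality age schedules are strongly regular across populations: a small
number of characteristic shapes (overall level, young-adult "accident hump",
mid-adult excess, ...) capture nearly all systematic variation.  Those shapes
are extracted as the right singular vectors of an *uncentred* N x A matrix of
log-mortality schedules (rows = region-subpopulation-year curves, columns =
age groups).  Leaving the matrix uncentred is deliberate: the first component
then tracks the overall level of mortality, so a single coefficient can shift
a whole curve up or down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReferenceMatrix:
    """Collection of log-mortality schedules used to build the basis.

    ``values`` is N x A (one row per region-subpopulation-year schedule, one
    column per age group, entries natural-log mortality rates).
    """

    values: np.ndarray
    row_labels: pd.DataFrame | None = None
    age_groups: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reference matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference matrix contains non-finite entries")
        n, a = self.values.shape
        if a < 2:
            raise ValueError("need at least 2 age groups")
        if n < a:
            raise ValueError("need at least as many schedules as age groups")
        if self.age_groups is None:
            self.age_groups = [str(i) for i in range(a)]
        if len(self.age_groups) != a:
            raise ValueError("age_groups length does not match column count")


@dataclass
class PCBasis:
    """Principal-component basis: columns of ``components`` are age schedules.

    ``components`` is A x P with unit-norm columns; ``left_values`` is N x P,
    the rows of U restricted to the retained components, so that
    ``left_values @ diag(singular_values) @ components.T`` reconstructs the
    rank-P approximation of the reference matrix.
    """

    components: np.ndarray
    singular_values: np.ndarray
    left_values: np.ndarray
    age_groups: Sequence[str] = field(default_factory=list)
    all_singular_values: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_ages(self) -> int:
        return self.components.shape[0]

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.left_values = np.asarray(self.left_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")
        if not len(self.age_groups):
            self.age_groups = [str(i) for i in range(self.components.shape[0])]


def _young_adult_index(age_groups: Sequence[str]) -> int:
    """Column index used to orient the accident-hump component.

    Looks for a '20-24' label (the convention for 5-year demographic age
    groups); falls back to one third of the way through the age range, which
    lands in young adulthood for schedules spanning infancy to 85+.
    """
    for i, g in enumerate(age_groups):
        if str(g).replace("–", "-") in ("20-24", "20_24", "20"):
            return i
    return max(2, len(age_groups) // 3)


def compute_svd_basis(
    X: ReferenceMatrix | np.ndarray,
    n_components: int = 4,
    sign_convention: str = "oriented",
) -> PCBasis:
    """Uncentred SVD of the reference matrix, truncated to ``n_components``.

    No column means are removed before the decomposition.  Under
    ``sign_convention='oriented'`` the first component is oriented to be
    elementwise non-positive (the characteristic "J" shape of log mortality)
    and the second to be positive at young-adult ages (the accident hump);
    the matching columns of ``left_values`` are negated so every product
    U_i * s_i * V_i' is unchanged.  ``'raw'`` leaves the backend output as is.
    """
    if not isinstance(X, ReferenceMatrix):
        X = ReferenceMatrix(np.asarray(X, dtype=float))
    n, a = X.values.shape
    if n_components > a:
        raise ValueError(f"n_components={n_components} exceeds {a} age groups")
    if n_components < 1:
        raise ValueError("n_components must be positive")
    if sign_convention not in ("raw", "oriented"):
        raise ValueError("sign_convention must be 'raw' or 'oriented'")
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    V = Vt.T
    comps = V[:, :n_components].copy()
    left = U[:, :n_components].copy()
    if sign_convention == "oriented":
        # PC1: force the overall-level component negative.
        if comps[:, 0].mean() > 0:
            comps[:, 0] *= -1.0
            left[:, 0] *= -1.0
        if n_components >= 2:
            ya = _young_adult_index(X.age_groups)
            if comps[ya, 1] < 0:
                comps[:, 1] *= -1.0
                left[:, 1] *= -1.0
    return PCBasis(
        components=comps,
        singular_values=s[:n_components].copy(),
        left_values=left,
        age_groups=list(X.age_groups),
        all_singular_values=s.copy(),
    )


def variance_explained(basis: PCBasis) -> np.ndarray:
    """Fraction of total (uncentred) variation carried by each component.

    Computed as sigma_i^2 / sum_j sigma_j^2 over all singular values of the
    original decomposition when available, else over the retained ones.
    """
    s_all = (
        basis.all_singular_values
        if basis.all_singular_values is not None
        else basis.singular_values
    )
    total = float(np.sum(np.asarray(s_all) ** 2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return np.asarray(basis.singular_values) ** 2 / total


def subgroup_separation(
    basis: PCBasis,
    subpop_labels: Sequence,
    max_components: int | None = None,
) -> pd.DataFrame:
    """Welch two-sample t-tests of left-singular-value location by subpopulation.

    The left singular values in column i measure how much component i
    contributes to each reference schedule; if a component carries
    subpopulation-specific structure, its coefficients separate by group.
    Components with small p-values are candidates for inclusion in the model.

    Returns one row per (component, subpopulation pair) with group means,
    the Welch statistic and its p-value.
    """
    labels = np.asarray(subpop_labels)
    if len(labels) != basis.left_values.shape[0]:
        raise ValueError("one label per row of left_values is required")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two subpopulations")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError(f"subpopulation {g!r} has fewer than 2 rows")
    p_max = max_components or basis.n_components
    p_max = min(p_max, basis.n_components)
    rows = []
    for i in range(p_max):
        col = basis.left_values[:, i]
        for ga, gb in combinations(groups, 2):
            xa, xb = col[labels == ga], col[labels == gb]
            res = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "component": i + 1,
                    "subpop_a": ga,
                    "subpop_b": gb,
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "statistic": float(res.statistic),
                    "pvalue": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)


class MortalityPCA:
    """Estimator wrapper around :func:`compute_svd_basis`.

    Follows scikit-learn conventions: constructor stores hyperparameters,
    :meth:`fit` computes the decomposition and exposes trailing-underscore
    attributes (``components_`` is P x A, scikit-learn orientation).
    """

    def __init__(self, n_components: int = 4, sign_convention: str = "oriented"):
        self.n_components = n_components
        self.sign_convention = sign_convention

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "sign_convention": self.sign_convention,
        }

    def set_params(self, **params) -> "MortalityPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: ReferenceMatrix | np.ndarray, y=None) -> "MortalityPCA":
        basis = compute_svd_basis(X, self.n_components, self.sign_convention)
        self.basis_ = basis
        self.components_ = basis.components.T
        self.singular_values_ = basis.singular_values
        self.left_values_ = basis.left_values
        self.explained_variance_ratio_ = variance_explained(basis)
        self.age_groups_ = list(basis.age_groups)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new log-mortality schedules onto the retained components."""
        if not hasattr(self, "basis_"):
            raise AttributeError("MortalityPCA instance is not fitted yet")
        X = np.asarray(X, dtype=float)
        return X @ self.basis_.components

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.left_values_ * self.singular_values_
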