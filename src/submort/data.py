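"""Death-count / exposure container indexed by age x subpopulation x area x year."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

LONG_COLUMNS = ["year", "area", "subpopulation", "age_group", "deaths", "population"]


@dataclass
class MortalityDataset:
    """Observed deaths and person-year exposures on a complete 4-d grid.

    Arrays are indexed ``(age, subpopulation, area, year)``.  ``mask`` marks
    cells that enter the likelihood; cells with zero exposure are always
    excluded, and hold-out validation additionally masks observed cells whose
    death counts are to be predicted out of sample.
    """

    deaths: np.ndarray
    exposures: np.ndarray
    ages: Sequence[str]
    subpops: Sequence[str]
    areas: Sequence[str]
    years: Sequence
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.exposures = np.asarray(self.exposures, dtype=float)
        shape = (len(self.ages), len(self.subpops), len(self.areas), len(self.years))
        if self.deaths.shape != shape or self.exposures.shape != shape:
            raise ValueError(
                f"array shapes {self.deaths.shape}/{self.exposures.shape} "
                f"do not match index sets {shape}"
            )
        if np.any(self.deaths < 0):
            raise ValueError("negative death counts")
        if np.any(self.exposures < 0):
            raise ValueError("negative exposures")
        if not np.issubdtype(self.deaths.dtype, np.integer):
            rounded = np.rint(self.deaths)
            if not np.allclose(self.deaths, rounded):
                raise ValueError("death counts must be integers")
            self.deaths = rounded.astype(np.int64)
        if np.any((self.exposures == 0) & (self.deaths > 0)):
            raise ValueError("deaths observed in cells with zero exposure")
        if self.mask is None:
            self.mask = self.exposures > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & (self.exposures > 0)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.deaths.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def copy(self) -> "MortalityDataset":
        return MortalityDataset(
            deaths=self.deaths.copy(),
            exposures=self.exposures.copy(),
            ages=list(self.ages),
            subpops=list(self.subpops),
            areas=list(self.areas),
            years=list(self.years),
            mask=self.mask.copy(),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with one row per cell (year, area, subpop, age)."""
        A, S, C, T = self.shape
        ai, si, ci, ti = np.meshgrid(
            np.arange(A), np.arange(S), np.arange(C), np.arange(T), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": np.asarray(self.years)[ti.ravel()],
                "area": np.asarray(self.areas)[ci.ravel()],
                "subpopulation": np.asarray(self.subpops)[si.ravel()],
                "age_group": np.asarray(self.ages)[ai.ravel()],
                "deaths": self.deaths.ravel(),
                "population": self.exposures.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "MortalityDataset":
        """Build a dataset from a long-format frame; the grid must be complete.

        Age-group and year orderings follow first appearance in the file for
        ages (so callers control demographic ordering) and sorted order for
        years.
        """
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        ages = list(pd.unique(df["age_group"]))
        subpops = sorted(pd.unique(df["subpopulation"]), key=str)
        areas = sorted(pd.unique(df["area"]), key=str)
        years = sorted(pd.unique(df["year"]))
        shape = (len(ages), len(subpops), len(areas), len(years))
        n_expected = int(np.prod(shape))
        key_cols = ["age_group", "subpopulation", "area", "year"]
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            raise ValueError(f"duplicate cells at rows {list(df.index[dup][:5])}")
        if len(df) != n_expected:
            have = set(map(tuple, df[key_cols].itertuples(index=False)))
            want = {
                (a, s, c, t) for a in ages for s in subpops for c in areas for t in years
            }
            absent = sorted(want - have, key=str)[:10]
            raise ValueError(
                f"incomplete grid: {n_expected - len(df)} missing cells, "
                f"first absentees: {absent}"
            )
        neg = df.index[(df["deaths"] < 0) | (df["population"] < 0)]
        if len(neg):
            raise ValueError(f"negative deaths or population at rows {list(neg[:5])}")
        a_idx = pd.Categorical(df["age_group"], categories=ages).codes
        s_idx = pd.Categorical(df["subpopulation"], categories=subpops).codes
        c_idx = pd.Categorical(df["area"], categories=areas).codes
        t_idx = pd.Categorical(df["year"], categories=years).codes
        deaths = np.zeros(shape, dtype=np.int64)
        expo = np.zeros(shape, dtype=float)
        deaths[a_idx, s_idx, c_idx, t_idx] = df["deaths"].to_numpy()
        expo[a_idx, s_idx, c_idx, t_idx] = df["population"].to_numpy()
        return cls(deaths=deaths, exposures=expo, ages=ages, subpops=subpops,
                   areas=areas, years=years)
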