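"""CSV/YAML readers and writers plus run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .basis import PCBasis, ReferenceMatrix
from .data import LONG_COLUMNS, MortalityDataset

FLOAT_FORMAT = "%.6g"  # fixed significant digits for reproducible diffs


def read_mortality_csv(path: str | Path) -> MortalityDataset:
    """Read a long-format deaths/exposures CSV into a validated dataset.

    Required columns: year, area, subpopulation, age_group, deaths,
    population.  Negative values and incomplete grids are rejected with the
    offending rows named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[(df["deaths"] < 0) | (df["population"] < 0)]
    if len(bad):
        # +2: header line and 1-based numbering
        rows = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"{path}: negative deaths or population at lines {rows}")
    frac = df["deaths"] % 1
    nonint = df.index[frac != 0]
    if len(nonint):
        rows = [int(i) + 2 for i in nonint[:10]]
        raise ValueError(f"{path}: non-integer deaths at lines {rows}")
    try:
        return MortalityDataset.from_long(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_mortality_csv(data: MortalityDataset, path: str | Path) -> None:
    data.to_long().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_reference_csv(path: str | Path) -> ReferenceMatrix:
    """Read a reference matrix CSV: region, subpopulation, year, then one
    column of log mortality rates per age group."""
    df = pd.read_csv(path)
    label_cols = ["region", "subpopulation", "year"]
    missing = [c for c in label_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing label columns {missing}")
    age_cols = [c for c in df.columns if c not in label_cols]
    if len(age_cols) < 2:
        raise ValueError(f"{path}: expected at least 2 age-group columns")
    return ReferenceMatrix(
        values=df[age_cols].to_numpy(dtype=float),
        row_labels=df[label_cols].copy(),
        age_groups=age_cols,
    )


def write_basis_csv(basis: PCBasis, stem: str | Path) -> list[Path]:
    """Write basis, singular-value, and left-value CSVs next to ``stem``."""
    stem = Path(stem)
    paths = []
    comp = pd.DataFrame(
        basis.components,
        columns=[f"PC{i + 1}" for i in range(basis.n_components)],
    )
    comp.insert(0, "age_group", list(basis.age_groups))
    p = stem.with_suffix(".components.csv")
    comp.to_csv(p, index=False, float_format=FLOAT_FORMAT)
    paths.append(p)
    sv = pd.DataFrame(
        {
            "component": np.arange(1, len(basis.singular_values) + 1),
            "singular_value": basis.singular_values,
        }
    )
    p = stem.with_suffix(".singular_values.csv")
    sv.to_csv(p, index=False, float_format=FLOAT_FORMAT)
    paths.append(p)
    return paths


def read_basis_csv(components_path: str | Path, singular_values_path: str | Path | None = None) -> PCBasis:
    comp = pd.read_csv(components_path)
    age = comp["age_group"].astype(str).tolist()
    pcs = [c for c in comp.columns if c.startswith("PC")]
    values = comp[pcs].to_numpy(dtype=float)
    if singular_values_path is not None:
        sv = pd.read_csv(singular_values_path)["singular_value"].to_numpy(dtype=float)[
            : len(pcs)
        ]
    else:
        sv = np.ones(len(pcs))
    return PCBasis(
        components=values,
        singular_values=sv,
        left_values=np.eye(len(pcs)),
        age_groups=age,
    )


def read_config_file(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, input digests, outputs."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    sampler_meta: dict = field(default_factory=dict)
    version: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        from . import __version__

        self.version = self.version or __version__
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")
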