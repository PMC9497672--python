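"""Synthetic fixtures with planted structure, CSV readers, config, logging.

The generator plants three kinds of columns so selection quality can be
scored against known ground truth: *informative* features drawn
class-conditionally (adjacent class means separated by ``class_signal``
standard deviations of the unit within-class noise), *redundant* features
that are noisy copies of informative parents (perturbation sd
``redundancy_noise``), and *noise* features independent of the class. This
emulates the relevant/redundant/irrelevant mixtures, binary and multiclass
targets, and observations-to-features regimes that real tabular benchmarks
stress, without any downloads.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .mi_core import (
    CategoricalSeries,
    DatasetTable,
    DiscretizationSpec,
    discretize_equal_frequency,
)

__all__ = [
    "PlantedSpec",
    "PlantedDataset",
    "generate_planted_dataset",
    "read_csv_dataset",
    "dataset_to_frame",
    "load_config",
    "setup_logging",
    "MissingTargetError",
    "MissingValuesError",
]

logger = logging.getLogger("mitn")


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr; idempotent."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


class MissingTargetError(ValueError):
    """The requested target column is absent from the file."""


class MissingValuesError(ValueError):
    """Input columns contain missing values; the caller must impute or drop."""


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted-structure generator.

    class_signal is the separation of adjacent class means in units of the
    unit within-class standard deviation; redundancy_noise is the sd of the
    perturbation added to a redundant feature's informative parent.
    """

    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 40
    n_obs: int = 500
    n_classes: int = 2
    class_signal: float = 2.0
    redundancy_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValueError("need >= 1 feature")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need informative parents")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if self.n_obs < 10 * self.n_classes:
            raise ValueError("need n_obs >= 10 * n_classes")
        if self.class_signal < 0 or self.redundancy_noise < 0:
            raise ValueError("signal and noise levels must be >= 0")


@dataclass(frozen=True)
class PlantedDataset:
    """A generated table plus the ground-truth role of every feature."""

    table: DatasetTable
    roles: tuple[str, ...]          # "informative" | "redundant" | "noise"
    parents: dict[int, int]         # redundant feature index -> parent index
    raw: pd.DataFrame               # undiscretized columns plus "class"

    @property
    def informative(self) -> frozenset[int]:
        return frozenset(i for i, r in enumerate(self.roles) if r == "informative")


def generate_planted_dataset(
    spec: PlantedSpec = PlantedSpec(),
    discretization: DiscretizationSpec = DiscretizationSpec(),
) -> PlantedDataset:
    """Draw a dataset with planted informative/redundant/noise features."""
    rng = np.random.default_rng(spec.seed)
    y = rng.integers(0, spec.n_classes, size=spec.n_obs)
    cols, names, roles = [], [], []
    parents: dict[int, int] = {}
    for i in range(spec.n_informative):
        x = y * spec.class_signal + rng.standard_normal(spec.n_obs)
        cols.append(x)
        names.append(f"inf{i}")
        roles.append("informative")
    for r in range(spec.n_redundant):
        parent = r % spec.n_informative
        x = cols[parent] + spec.redundancy_noise * rng.standard_normal(spec.n_obs)
        parents[len(cols)] = parent
        cols.append(x)
        names.append(f"red{r}")
        roles.append("redundant")
    for k in range(spec.n_noise):
        cols.append(rng.standard_normal(spec.n_obs))
        names.append(f"noise{k}")
        roles.append("noise")
    raw = pd.DataFrame({name: col for name, col in zip(names, cols)})
    raw["class"] = y
    features = tuple(discretize_equal_frequency(c, discretization) for c in cols)
    table = DatasetTable(
        features=features, names=tuple(names),
        class_column=CategoricalSeries.from_values(y),
    )
    logger.debug("generated planted dataset: %d obs, %d features, %d classes",
                 spec.n_obs, len(names), spec.n_classes)
    return PlantedDataset(table=table, roles=tuple(roles), parents=parents, raw=raw)


def read_csv_dataset(
    path: str | Path,
    target_column: str,
    discretization: DiscretizationSpec = DiscretizationSpec(),
) -> DatasetTable:
    """Read a delimited table; discretize continuous predictors, encode the rest."""
    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise MissingTargetError(
            f"target column {target_column!r} not in {list(df.columns)}")
    with_na = [c for c in df.columns if df[c].isna().any()]
    if with_na:
        raise MissingValuesError(f"columns with missing values: {with_na}")
    features, names = [], []
    for col in df.columns:
        if col == target_column:
            continue
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            features.append(discretize_equal_frequency(s.to_numpy(float), discretization))
        else:
            features.append(CategoricalSeries.from_values(s.to_numpy()))
        names.append(col)
    table = DatasetTable(
        features=tuple(features), names=tuple(names),
        class_column=CategoricalSeries.from_values(df[target_column].to_numpy()),
    )
    logger.info("read %s: %d rows, %d predictors, target %r",
                path, table.n_obs, table.n_features, target_column)
    return table


def dataset_to_frame(ds: PlantedDataset) -> pd.DataFrame:
    """The raw (undiscretized) generated table, ready for to_csv round trips."""
    return ds.raw.copy()


def load_config(path: str | Path) -> dict:
    """YAML config mirroring the CLI flags; returns a flat dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def cli_main(args: Optional[list[str]] = None) -> int:
    """Entry point for the command-line interface (see mitn.cli)."""
    from .cli import cli_main as _cli_main  # deferred: cli imports this module

    return _cli_main(args)
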