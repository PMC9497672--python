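"""Plug-in information estimates on discretized data columns.

Everything downstream — the greedy criteria, the transfer network, the MILP
objective — is built from the quantities here: Shannon entropy, joint and
conditional entropy, mutual information (MI), conditional MI and the
three-way interaction information, all estimated by the maximum-likelihood
(plug-in) estimator on empirical contingency tables and reported in bits.

Continuous columns are reduced to categorical codes by equal-frequency
(quantile) binning before any estimate is taken; columns with few distinct
values are treated as already categorical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CategoricalSeries",
    "DatasetTable",
    "DiscretizationSpec",
    "discretize_equal_frequency",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "joint_variable",
]


class NonFiniteValueError(ValueError):
    """A column handed to the discretizer contains NaN or infinity."""


class EmptyColumnError(ValueError):
    """A column or series with no observations was supplied."""


class LengthMismatchError(ValueError):
    """Series of different lengths were combined."""


@dataclass(frozen=True)
class CategoricalSeries:
    """A discrete variable as non-negative integer category codes.

    Parameters
    ----------
    codes
        Integer codes, one per observation; every code is < ``n_levels``.
    n_levels
        Number of category levels. Levels need not all be observed.
    """

    codes: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size == 0:
            raise EmptyColumnError("a CategoricalSeries needs >= 1 observation")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if codes.min() < 0 or codes.max() >= self.n_levels:
            raise ValueError("codes must lie in [0, n_levels)")

    @property
    def n_obs(self) -> int:
        return int(self.codes.size)

    @classmethod
    def from_values(cls, values: Sequence) -> "CategoricalSeries":
        """Encode arbitrary hashable values to dense codes (sorted order)."""
        arr = np.asarray(values)
        if arr.size == 0:
            raise EmptyColumnError("empty column")
        _, codes = np.unique(arr, return_inverse=True)
        return cls(codes=codes.astype(np.int64), n_levels=int(codes.max()) + 1)


@dataclass(frozen=True)
class DatasetTable:
    """Encoded predictors plus a class column; the unit every method consumes."""

    features: tuple[CategoricalSeries, ...]
    names: tuple[str, ...]
    class_column: CategoricalSeries

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("need >= 1 feature")
        if len(self.names) != len(self.features):
            raise ValueError("one name per feature required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        n_obs = self.class_column.n_obs
        for s in self.features:
            if s.n_obs != n_obs:
                raise LengthMismatchError("all columns must share n_obs")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_obs(self) -> int:
        return self.class_column.n_obs


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous columns are reduced to categories.

    ``n_bins`` equal-frequency bins are used for columns with more than
    ``continuity_threshold`` distinct values; anything at or below the
    threshold is passed through as categorical unchanged.
    """

    n_bins: int = 5
    continuity_threshold: int = 21

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.continuity_threshold < 1:
            raise ValueError("continuity_threshold must be >= 1")


def discretize_equal_frequency(
    column: Sequence[float], spec: DiscretizationSpec = DiscretizationSpec()
) -> CategoricalSeries:
    """Quantile-bin a numeric column into at most ``spec.n_bins`` codes.

    Bin boundaries are quantiles of the *distinct* values, so identical
    input values can never straddle a boundary and the coding is
    deterministic. Columns with fewer than ``spec.continuity_threshold``
    distinct values are treated as categorical and encoded unchanged.
    """
    arr = np.asarray(column, dtype=float)
    if arr.size == 0:
        raise EmptyColumnError("empty column")
    if not np.all(np.isfinite(arr)):
        raise NonFiniteValueError("column contains NaN or infinite values")
    distinct = np.unique(arr)
    if distinct.size <= spec.continuity_threshold:
        _, codes = np.unique(arr, return_inverse=True)
        return CategoricalSeries(codes=codes.astype(np.int64), n_levels=distinct.size)
    # interior boundaries at quantiles j/n_bins of the distinct values
    qs = np.arange(1, spec.n_bins) / spec.n_bins
    edges = np.quantile(distinct, qs)
    codes = np.searchsorted(edges, arr, side="left")
    # re-densify in case some bins are empty
    _, codes = np.unique(codes, return_inverse=True)
    return CategoricalSeries(codes=codes.astype(np.int64), n_levels=int(codes.max()) + 1)


def _plugin_entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(s: CategoricalSeries) -> float:
    """Shannon entropy H(X) = -sum p_i log2 p_i, in bits, with 0 log 0 := 0."""
    counts = np.bincount(s.codes, minlength=s.n_levels)
    return _plugin_entropy_from_counts(counts)


def _check_lengths(*series: CategoricalSeries) -> int:
    n = series[0].n_obs
    for s in series[1:]:
        if s.n_obs != n:
            raise LengthMismatchError("series lengths differ")
    return n


def joint_variable(a: CategoricalSeries, b: CategoricalSeries) -> CategoricalSeries:
    """The paired variable (A,B): one code per distinct observed pair."""
    _check_lengths(a, b)
    flat = a.codes * b.n_levels + b.codes
    _, codes = np.unique(flat, return_inverse=True)
    return CategoricalSeries(codes=codes.astype(np.int64), n_levels=int(codes.max()) + 1)


def joint_entropy(ss: Sequence[CategoricalSeries]) -> float:
    """Entropy of the tuple-valued variable formed by aligning rows."""
    if len(ss) == 0:
        raise ValueError("need >= 1 series")
    joint = ss[0]
    for s in ss[1:]:
        joint = joint_variable(joint, s)
    return entropy(joint)


def conditional_entropy(x: CategoricalSeries, y: CategoricalSeries) -> float:
    """H(X|Y) = H(X,Y) - H(Y); lies in [0, H(X)]."""
    _check_lengths(x, y)
    return joint_entropy([x, y]) - entropy(y)


def mutual_information(x: CategoricalSeries, y: CategoricalSeries) -> float:
    """I(X;Y) = H(X) - H(X|Y), clipped to be non-negative against roundoff."""
    _check_lengths(x, y)
    i = entropy(x) - conditional_entropy(x, y)
    return max(i, 0.0)


def conditional_mutual_information(
    x: CategoricalSeries, y: CategoricalSeries, z: CategoricalSeries
) -> float:
    """I(X;Y|Z) = H(X|Z) - H(X|Y,Z); non-negative for the plug-in estimate."""
    _check_lengths(x, y, z)
    yz = joint_variable(y, z)
    i = conditional_entropy(x, z) - (joint_entropy([x, yz]) - entropy(yz))
    return max(i, 0.0)


def interaction_information(
    x: CategoricalSeries, y: CategoricalSeries, z: CategoricalSeries
) -> float:
    """Three-way interaction I(X;Y;Z) = I(X;Y) - I(X;Y|Z).

    Symmetric under permutation of the arguments; negative values indicate
    synergy (the XOR triple attains -1 bit).
    """
    _check_lengths(x, y, z)
    return mutual_information(x, y) - conditional_mutual_information(x, y, z)
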