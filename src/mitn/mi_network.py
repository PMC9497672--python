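"""The MI transfer network: pairwise-MI capacities and class-MI supplies.

A dataset with n features and class C becomes a flow network: feature node i
carries a supply ``b[i] = I(f_i; C)`` (the class information it holds) and
the arc between features i and j has capacity ``U[i][j] = I(f_i; f_j)`` (the
information they can exchange). Two extra nodes exist implicitly: a target T
that collects information through a single selected terminal feature, and a
dummy drain D that absorbs undelivered supply so flow balances. The
"infinite" capacity of the arcs into D and T is represented by the finite
``big_M``: total flow can never exceed the total supply, so ``sum(b)`` is
capacity-equivalent and keeps the solver's matrices finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mi_core import DatasetTable, mutual_information

__all__ = ["MITransferNetwork", "BoundVector", "build_network", "compute_upper_bounds"]


@dataclass(frozen=True)
class MITransferNetwork:
    """Symmetric MI matrix U (zero diagonal), supply vector b, labels, big_M."""

    U: np.ndarray
    b: np.ndarray
    names: tuple[str, ...]
    big_M: float

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "b", b)
        n = b.size
        if U.shape != (n, n) or len(self.names) != n:
            raise ValueError("U, b and names must agree in size")
        if not np.allclose(U, U.T):
            raise ValueError("U must be symmetric")
        if np.any(np.diag(U) != 0.0):
            raise ValueError("U must have an exactly zero diagonal")
        if U.min() < 0 or b.min() < 0:
            raise ValueError("MI values must be non-negative")
        if not np.isfinite(self.big_M) or self.big_M < b.sum() - 1e-12:
            raise ValueError("big_M must be finite and >= sum(b)")

    @property
    def n(self) -> int:
        return int(self.b.size)

    def scaled(self, c: float) -> "MITransferNetwork":
        """The network with every information value multiplied by c > 0."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return MITransferNetwork(self.U * c, self.b * c, self.names, max(self.big_M * c, 1.0))

    def to_json(self, path: str | Path) -> None:
        payload = {"names": list(self.names), "U": self.U.tolist(),
                   "b": self.b.tolist(), "big_M": self.big_M}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MITransferNetwork":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["U"]), np.array(d["b"]), tuple(d["names"]), float(d["big_M"]))


@dataclass(frozen=True)
class BoundVector:
    """Per-terminal caps on flow into T, precomputed for a selection size P.

    ``k[i]`` bounds the total information deliverable to T when feature i is
    the terminal: the terminal's own supply plus either the top-(P-1) arc
    capacities into it or the top-(P-1) supplies of the other features,
    whichever is smaller.
    """

    k: np.ndarray
    P: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if self.P < 1:
            raise ValueError("P must be >= 1")


def build_network(data: DatasetTable) -> MITransferNetwork:
    """Compute U and b from a dataset by plug-in MI on every pair of columns."""
    n = data.n_features
    U = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            U[i, j] = U[j, i] = mutual_information(data.features[i], data.features[j])
    b = np.array([mutual_information(f, data.class_column) for f in data.features])
    total = float(b.sum())
    return MITransferNetwork(U=U, b=b, names=data.names, big_M=total if total > 0 else 1.0)


def _top_sum(values: np.ndarray, count: int) -> float:
    if count <= 0:
        return 0.0
    if count >= values.size:
        return float(values.sum())
    return float(np.sort(values)[-count:].sum())


def compute_upper_bounds(network: MITransferNetwork, P: int) -> BoundVector:
    """The per-terminal bound k_i for selection size P.

    k_i = min( b_i + sum of top (P-1) of {U[j][i] : j != i},
               b_i + sum of top (P-1) of {b[j]    : j != i} )

    The candidate range for j is all other features — a relaxation of the
    (unknowable before solving) unselected set, so k stays precomputable and
    remains a valid upper bound.
    """
    n = network.n
    if not 1 <= P <= n:
        raise ValueError(f"P must lie in [1, {n}], got {P}")
    k = np.empty(n)
    for i in range(n):
        others = np.arange(n) != i
        cap_term = network.b[i] + _top_sum(network.U[others, i], P - 1)
        sup_term = network.b[i] + _top_sum(network.b[others], P - 1)
        k[i] = min(cap_term, sup_term)
    return BoundVector(k=k, P=P)
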