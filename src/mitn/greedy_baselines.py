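"""MI-based greedy forward selection: one engine, seven pluggable criteria.

Each method picks features incrementally. At every step the unselected
feature maximizing

    J(f) = I(C; f) - beta * sum_{f_i in SEL} g(f, f_i, C)

is added, where the (beta rule, g function) pair defines the method:

    MIFS-U    beta = user parameter     g = I(f_i;C)/H(f_i) * I(f;f_i)
    IGFS      beta = -1/|SEL|           g = I(f; (C,f_i))
    CIFE      beta = 1                  g = I(f_i; (C,f))
    MRMD      beta = 1/|SEL|            g = I(f;f_i) - I(f;C|f_i)
    MRI       beta = 1                  g = 2*I(f;f_i;C) - I(f;C) - I(f_i;C)
    mRMR      beta = 1/|SEL|            g = I(f;f_i)
    SPEC-CMI  beta = -1                 g = I(f;C|f_i)

The first pick is always argmax I(C;f) (the penalty sum is empty). Selecting
m of n features costs n + (n-1) + ... + (n-m+1) = (2n-m+1)m/2 criterion
evaluations, against C(n,m) subsets for exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .mi_core import (
    CategoricalSeries,
    DatasetTable,
    conditional_mutual_information,
    entropy,
    interaction_information,
    joint_variable,
    mutual_information,
)

__all__ = [
    "GreedyCriterion",
    "GreedySelectionTrace",
    "make_criterion",
    "CRITERION_NAMES",
    "greedy_select",
    "criterion_score",
    "evaluation_count",
]

CRITERION_NAMES = ("MIFS-U", "IGFS", "CIFE", "MRMD", "MRI", "mRMR", "SPEC-CMI")


@dataclass(frozen=True)
class GreedyCriterion:
    """A (beta rule, g function) pair realizing one greedy forward method."""

    name: str
    beta_rule: Callable[[int], float]  # |SEL| -> beta
    g: Callable[[CategoricalSeries, CategoricalSeries, CategoricalSeries], float]


@dataclass(frozen=True)
class GreedySelectionTrace:
    """Selection order, per-pick criterion values, and evaluation count."""

    selected_order: tuple[int, ...]
    scores: tuple[float, ...]
    evaluations: int


def _g_mifs_u(f, fi, C):
    h = entropy(fi)
    if h == 0.0:  # constant feature: both MI factors are zero anyway
        return 0.0
    return mutual_information(fi, C) / h * mutual_information(f, fi)


def _g_igfs(f, fi, C):
    return mutual_information(f, joint_variable(C, fi))


def _g_cife(f, fi, C):
    return mutual_information(fi, joint_variable(C, f))


def _g_mrmd(f, fi, C):
    return mutual_information(f, fi) - conditional_mutual_information(f, C, fi)


def _g_mri(f, fi, C):
    return (2.0 * interaction_information(f, fi, C)
            - mutual_information(f, C) - mutual_information(fi, C))


def _g_mrmr(f, fi, C):
    return mutual_information(f, fi)


def _g_spec_cmi(f, fi, C):
    return conditional_mutual_information(f, C, fi)


def make_criterion(name: str, beta: Optional[float] = None) -> GreedyCriterion:
    """Build a named criterion; MIFS-U requires an explicit beta."""
    key = name.upper().replace("_", "-")
    if key == "MRMR":
        key = "mRMR"
    if key == "MIFS-U":
        if beta is None:
            raise ValueError("MIFS-U requires a beta value")
        b = float(beta)
        return GreedyCriterion("MIFS-U", lambda m: b, _g_mifs_u)
    table = {
        "IGFS": (lambda m: -1.0 / m, _g_igfs),
        "CIFE": (lambda m: 1.0, _g_cife),
        "MRMD": (lambda m: 1.0 / m, _g_mrmd),
        "MRI": (lambda m: 1.0, _g_mri),
        "mRMR": (lambda m: 1.0 / m, _g_mrmr),
        "SPEC-CMI": (lambda m: -1.0, _g_spec_cmi),
    }
    if key not in table:
        raise ValueError(f"unknown criterion {name!r}; choose from {CRITERION_NAMES}")
    beta_rule, g = table[key]
    return GreedyCriterion(key, beta_rule, g)


def criterion_score(f_idx: int, sel: list[int], data: DatasetTable,
                    criterion: GreedyCriterion) -> float:
    """J(f) for one candidate given the currently selected set."""
    if f_idx in sel:
        raise ValueError("candidate already selected")
    f = data.features[f_idx]
    C = data.class_column
    score = mutual_information(C, f)
    if sel:
        beta = criterion.beta_rule(len(sel))
        score -= beta * sum(criterion.g(f, data.features[i], C) for i in sel)
    return score


def greedy_select(data: DatasetTable, m: int,
                  criterion: GreedyCriterion) -> GreedySelectionTrace:
    """Forward selection of m features; ties broken by smallest index."""
    n = data.n_features
    if not 1 <= m <= n:
        raise ValueError(f"m must lie in [1, {n}], got {m}")
    sel: list[int] = []
    scores: list[float] = []
    evaluations = 0
    remaining = list(range(n))
    while len(sel) < m:
        best_idx, best_score = None, None
        for f_idx in remaining:
            s = criterion_score(f_idx, sel, data, criterion)
            evaluations += 1
            if best_score is None or s > best_score:
                best_idx, best_score = f_idx, s
        sel.append(best_idx)
        scores.append(best_score)
        remaining.remove(best_idx)
    return GreedySelectionTrace(tuple(sel), tuple(scores), evaluations)


def evaluation_count(n: int, m: int) -> int:
    """Criterion evaluations needed to pick m of n features: (2n-m+1)m/2."""
    if not 1 <= m <= n:
        raise ValueError(f"m must lie in [1, {n}], got {m}")
    return (2 * n - m + 1) * m // 2
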