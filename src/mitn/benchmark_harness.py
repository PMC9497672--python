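"""Accuracy benchmarking of feature-selection methods across classifiers.

The protocol: each method selects subsets over a grid of selection sizes P;
every subset is scored by stratified k-fold cross-validated accuracy under
four off-the-shelf classifier families — nearest-neighbor, naive Bayes,
max-margin linear (linear SVM) and linear discriminant analysis — so no
single classifier's inductive bias decides the comparison. Per-(method, P)
performance is the mean accuracy over families, and methods are ranked in
descending accuracy within each (classifier, P) cell, ties sharing the
better rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .greedy_baselines import GreedyCriterion, greedy_select
from .mi_core import DatasetTable
from .milp_selector import MILPConfig, select_features

__all__ = [
    "DEFAULT_FAMILIES",
    "BenchmarkResult",
    "evaluate_subset",
    "run_grid",
    "rank_methods",
    "mitn_method",
    "greedy_method",
]

DEFAULT_FAMILIES = ("knn", "naive_bayes", "linear_svm", "lda")


def _make_classifier(family: str, seed: int):
    if family == "knn":
        return KNeighborsClassifier()
    if family == "naive_bayes":
        return GaussianNB()
    if family == "linear_svm":
        return LinearSVC(random_state=seed)
    if family == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass(frozen=True)
class BenchmarkResult:
    """Tidy accuracy grid plus per-(method, P) metadata (e.g. achieved gap)."""

    cells: pd.DataFrame      # columns: method, P, classifier, accuracy
    meta: dict               # (method, P) -> dict (subset, gap, errors, ...)
    config: dict

    def mean_accuracy(self) -> pd.DataFrame:
        """Mean accuracy over classifier families per (method, P)."""
        return (self.cells.groupby(["method", "P"], as_index=False)["accuracy"]
                .mean().rename(columns={"accuracy": "mean_accuracy"}))

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def evaluate_subset(
    data: DatasetTable,
    subset: Iterable[int],
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold accuracy of each classifier family on one subset."""
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("subset must be non-empty")
    X = np.column_stack([data.features[i].codes for i in subset]).astype(float)
    y = data.class_column.codes
    counts = np.bincount(y)
    thin = np.flatnonzero((counts > 0) & (counts < cv_folds))
    if thin.size:
        raise ValueError(
            f"classes {thin.tolist()} have fewer than cv_folds={cv_folds} members; "
            "reduce cv_folds or merge rare classes")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear LDA / SVM convergence chatter
        for family in families:
            clf = _make_classifier(family, seed)
            out[family] = float(cross_val_score(clf, X, y, cv=cv).mean())
    out["mean"] = float(np.mean([out[f] for f in families]))
    return out


def mitn_method(config: MILPConfig = MILPConfig()) -> Callable:
    """A grid-ready selector running the transfer-network MILP."""

    def _run(data: DatasetTable, P: int):
        result, _ = select_features(data, P, config)
        return sorted(result.selected), {"gap": result.achieved_gap,
                                         "status": result.status,
                                         "objective_bits": result.objective}

    return _run


def greedy_method(criterion: GreedyCriterion) -> Callable:
    """A grid-ready selector running one greedy forward criterion."""

    def _run(data: DatasetTable, P: int):
        trace = greedy_select(data, P, criterion)
        return sorted(trace.selected_order), {"evaluations": trace.evaluations}

    return _run


def run_grid(
    data: DatasetTable,
    methods: dict[str, Callable],
    P_grid: Iterable[int] = tuple(range(5, 55, 5)),
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    cv_folds: int = 5,
    seed: int = 0,
) -> BenchmarkResult:
    """Evaluate every (method, P) with identical folds; failures are recorded
    per cell and the grid continues."""
    P_grid = sorted(set(int(p) for p in P_grid))
    if max(P_grid) > data.n_features:
        raise ValueError("max(P_grid) exceeds the number of features")
    rows, meta = [], {}
    for name, method in methods.items():
        for P in P_grid:
            try:
                subset, info = method(data, P)
                accs = evaluate_subset(data, subset, families, cv_folds, seed)
                meta[(name, P)] = {"subset": list(subset), **info}
                for family in families:
                    rows.append({"method": name, "P": P, "classifier": family,
                                 "accuracy": accs[family]})
            except Exception as exc:  # a failed cell must not kill the sweep
                meta[(name, P)] = {"error": f"{type(exc).__name__}: {exc}"}
                for family in families:
                    rows.append({"method": name, "P": P, "classifier": family,
                                 "accuracy": np.nan})
    config = {"cv_folds": cv_folds, "seed": seed, "families": list(families),
              "of_ratio": data.n_obs / data.n_features,
              "classifier_hyperparameters": "library defaults"}
    return BenchmarkResult(cells=pd.DataFrame(rows), meta=meta, config=config)


def rank_methods(result: BenchmarkResult) -> pd.DataFrame:
    """Descending-accuracy rank within each (classifier, P) cell; ties share
    the better rank."""
    n_methods = result.cells["method"].nunique()
    if n_methods < 2:
        raise ValueError("ranking needs >= 2 methods")
    out = result.cells.copy()
    out["rank"] = (out.groupby(["classifier", "P"])["accuracy"]
                   .rank(ascending=False, method="min"))
    return out
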