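"""Gated maximum-flow MILP for selecting P features, plus an exhaustive oracle.

Selecting P features is cast as a maximum-flow problem on the MI transfer
network: binary y marks the P selected features, binary v marks the single
terminal feature allowed to deliver into the target T, and continuous arc
flows x move information (in bits) between selected features, into T, or
into the drain D. The model maximizes total flow into T:

    max   sum_i x_iT
    s.t.  (C1) sum_i y_i = P
          (C2) sum_i v_i = 1
          (C3) v_i <= y_i
          (C4) sum_j x_ij + x_iD + x_iT - sum_j x_ji = b_i   (flow balance)
          (C5) x_ij <= U_ij * y_i   and   x_ij <= U_ij * y_j
          (C6) x_iT <= big_M * v_i
          (C7) x_iT <= k_i                                    (precomputed cap)

(C5) gates every feature-feature arc on both endpoints being selected, and
(C3)+(C6) let information exit only at the selected terminal; unselected
supply drains to D, which keeps the model always feasible. Multi-hop relays
among selected features are permitted — flow balance naturally allows them.

The solver backend is HiGHS branch-and-bound through scipy.optimize.milp,
terminated at a relative optimality gap (MIPGap); the exhaustive oracle
enumerates every P-subset and terminal and solves each induced max-flow
problem with networkx, giving an independent global optimum for small n.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .mi_core import DatasetTable
from .mi_network import BoundVector, MITransferNetwork, build_network, compute_upper_bounds

__all__ = [
    "MILPConfig",
    "SelectionResult",
    "MILPModel",
    "build_model",
    "solve",
    "validate_solution",
    "exhaustive_oracle",
    "select_features",
    "SolverBackendError",
    "OracleCapExceededError",
]

_TOL = 1e-6  # feasibility tolerance used when validating incumbents


class SolverBackendError(RuntimeError):
    """The MILP backend failed or returned no usable incumbent."""


class OracleCapExceededError(ValueError):
    """C(n, P) exceeds the enumeration cap; shrink n or P."""


@dataclass(frozen=True)
class MILPConfig:
    """Termination settings: relative gap tolerance, wall-clock limit, seed."""

    mip_gap: float = 0.05
    time_limit_seconds: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be >= 0")


@dataclass(frozen=True)
class SelectionResult:
    """A selection: the y=1 set, the terminal, arc flows and the objective.

    ``flow`` maps arcs to bits: ``(i, j)`` between features, ``(i, "D")``
    into the drain, ``(i, "T")`` into the target. ``objective`` is the total
    flow into T; ``achieved_gap`` the relative optimality gap reported by
    the solver (0 for the oracle).
    """

    selected: frozenset[int]
    terminal: int
    flow: dict
    objective: float
    achieved_gap: float
    status: str  # optimal | gap_reached | time_limit | infeasible

    def to_json(self, path: str | Path, names: Optional[tuple[str, ...]] = None) -> None:
        name = (lambda i: names[i]) if names is not None else (lambda i: f"f{i}")
        arcs = {f"{name(i) if isinstance(i, int) else i}->"
                f"{name(j) if isinstance(j, int) else j}": v
                for (i, j), v in self.flow.items() if v > 1e-12}
        payload = {
            "selected": sorted(name(i) for i in self.selected),
            "terminal": name(self.terminal),
            "objective_bits": self.objective,
            "achieved_gap": self.achieved_gap,
            "status": self.status,
            "flows_bits": arcs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class MILPModel:
    """The assembled model: variable layout, constraint matrix and bounds.

    Variable order: feature-feature flows x_ij (all ordered pairs i != j),
    then x_iD, x_iT, then binaries y_i, v_i.
    """

    network: MITransferNetwork
    P: int
    bounds: BoundVector
    c: np.ndarray
    constraints: LinearConstraint
    integrality: np.ndarray
    var_bounds: Bounds
    ff_index: dict  # (i, j) -> column
    n_ff: int

    @property
    def n(self) -> int:
        return self.network.n

    def column(self, kind: str, i: int) -> int:
        base = {"D": self.n_ff, "T": self.n_ff + self.n,
                "y": self.n_ff + 2 * self.n, "v": self.n_ff + 3 * self.n}[kind]
        return base + i

    def to_lp(self, path: str | Path) -> None:
        """Write the model in CPLEX LP format for debugging."""
        n, names = self.n, []
        for (i, j) in self.ff_index:
            names.append(f"x_{i}_{j}")
        names += [f"xD_{i}" for i in range(n)] + [f"xT_{i}" for i in range(n)]
        names += [f"y_{i}" for i in range(n)] + [f"v_{i}" for i in range(n)]
        A = sparse.csr_matrix(self.constraints.A)
        lb, ub = np.atleast_1d(self.constraints.lb), np.atleast_1d(self.constraints.ub)
        lines = ["Maximize", " obj: " + " + ".join(
            f"{-c:g} {names[k]}" for k, c in enumerate(self.c) if c != 0), "Subject To"]
        for r in range(A.shape[0]):
            row = A.getrow(r)
            terms = " + ".join(f"{v:g} {names[k]}" for k, v in zip(row.indices, row.data))
            terms = terms.replace("+ -", "- ")
            if lb[r] == ub[r]:
                lines.append(f" c{r}: {terms} = {ub[r]:g}")
            elif math.isfinite(ub[r]):
                lines.append(f" c{r}: {terms} <= {ub[r]:g}")
            else:
                lines.append(f" c{r}: {terms} >= {lb[r]:g}")
        lines.append("Bounds")
        vub = np.atleast_1d(self.var_bounds.ub)
        for k, name in enumerate(names):
            hi = "+inf" if not math.isfinite(vub[k]) else f"{vub[k]:g}"
            lines.append(f" 0 <= {name} <= {hi}")
        lines.append("Binaries")
        lines.append(" " + " ".join(names[self.n_ff + 2 * n:]))
        lines.append("End")
        Path(path).write_text("\n".join(lines) + "\n")


def build_model(network: MITransferNetwork, P: int, bounds: BoundVector) -> MILPModel:
    """Assemble the gated max-flow MILP for the given network and P."""
    n = network.n
    if not 1 <= P <= n:
        raise ValueError(f"P must lie in [1, {n}], got {P}")
    if bounds.k.size != n or bounds.P != P:
        raise ValueError("bounds were not computed for this network and P")

    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    ff_index = {p: k for k, p in enumerate(pairs)}
    n_ff = len(pairs)
    n_vars = n_ff + 4 * n
    col_D = lambda i: n_ff + i
    col_T = lambda i: n_ff + n + i
    col_y = lambda i: n_ff + 2 * n + i
    col_v = lambda i: n_ff + 3 * n + i

    c = np.zeros(n_vars)
    c[n_ff + n:n_ff + 2 * n] = -1.0  # maximize sum x_iT

    rows, cols, vals, lbs, ubs = [], [], [], [], []

    def add_row(entries, lo, hi):
        r = len(lbs)
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lbs.append(lo)
        ubs.append(hi)

    add_row([(col_y(i), 1.0) for i in range(n)], P, P)          # C1
    add_row([(col_v(i), 1.0) for i in range(n)], 1.0, 1.0)      # C2
    for i in range(n):                                          # C3
        add_row([(col_v(i), 1.0), (col_y(i), -1.0)], -np.inf, 0.0)
    for i in range(n):                                          # C4 balance
        entries = [(ff_index[(i, j)], 1.0) for j in range(n) if j != i]
        entries += [(col_D(i), 1.0), (col_T(i), 1.0)]
        entries += [(ff_index[(j, i)], -1.0) for j in range(n) if j != i]
        add_row(entries, network.b[i], network.b[i])
    for (i, j), k in ff_index.items():                          # C5 gating
        add_row([(k, 1.0), (col_y(i), -network.U[i, j])], -np.inf, 0.0)
        add_row([(k, 1.0), (col_y(j), -network.U[i, j])], -np.inf, 0.0)
    for i in range(n):                                          # C6 terminal gate
        add_row([(col_T(i), 1.0), (col_v(i), -network.big_M)], -np.inf, 0.0)

    A = sparse.csc_matrix((vals, (rows, cols)), shape=(len(lbs), n_vars))
    constraints = LinearConstraint(A, np.array(lbs), np.array(ubs))

    lb = np.zeros(n_vars)
    ub = np.full(n_vars, np.inf)
    ub[n_ff + n:n_ff + 2 * n] = bounds.k                         # C7 as variable bound
    ub[n_ff + 2 * n:] = 1.0
    integrality = np.zeros(n_vars)
    integrality[n_ff + 2 * n:] = 1

    return MILPModel(network=network, P=P, bounds=bounds, c=c,
                     constraints=constraints, integrality=integrality,
                     var_bounds=Bounds(lb, ub), ff_index=ff_index, n_ff=n_ff)


def solve(model: MILPModel, config: MILPConfig = MILPConfig()) -> SelectionResult:
    """Run branch-and-bound, stopping at the configured relative gap."""
    # mip_abs_gap=0 makes the relative gap the sole optimality criterion;
    # scipy forwards extra options to HiGHS verbatim with a RuntimeWarning we
    # silence. At gap 0 the caller wants proof-quality optimality, so the
    # feasibility tolerances are tightened too (the defaults let incumbents
    # overshoot the true optimum by ~1e-6).
    options: dict = {"mip_rel_gap": config.mip_gap, "mip_abs_gap": 0.0}
    if config.mip_gap == 0.0:
        options.update(primal_feasibility_tolerance=1e-9,
                       dual_feasibility_tolerance=1e-9,
                       mip_feasibility_tolerance=1e-9)
    if config.time_limit_seconds is not None:
        options["time_limit"] = config.time_limit_seconds
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Unrecognized options",
                                category=RuntimeWarning)
        res = milp(c=model.c, constraints=model.constraints,
                   integrality=model.integrality, bounds=model.var_bounds,
                   options=options)
    if res.status == 2:
        return SelectionResult(frozenset(), -1, {}, float("nan"), float("nan"), "infeasible")
    if res.x is None:
        raise SolverBackendError(f"solver returned no incumbent: {res.message}")

    n, n_ff = model.n, model.n_ff
    x = res.x
    y = x[n_ff + 2 * n:n_ff + 3 * n]
    v = x[n_ff + 3 * n:]
    selected = frozenset(int(i) for i in np.flatnonzero(y > 0.5))
    terminal = int(np.argmax(v))
    flow: dict = {}
    for (i, j), k in model.ff_index.items():
        if x[k] > 1e-12:
            flow[(i, j)] = float(x[k])
    for i in range(n):
        xd, xt = x[model.column("D", i)], x[model.column("T", i)]
        if xd > 1e-12:
            flow[(i, "D")] = float(xd)
        if xt > 1e-12:
            flow[(i, "T")] = float(xt)
    objective = float(sum(x[model.column("T", i)] for i in range(n)))
    gap = float(res.mip_gap) if res.mip_gap is not None else float("nan")
    if res.status == 1:
        status = "time_limit"
    else:
        status = "optimal" if gap <= 1e-6 else "gap_reached"
    return SelectionResult(selected, terminal, flow, objective, gap, status)


def validate_solution(result: SelectionResult, network: MITransferNetwork,
                      P: int) -> list[str]:
    """Check a result against every model constraint; returns violations."""
    violations = []
    n = network.n
    k = compute_upper_bounds(network, P).k
    if len(result.selected) != P:
        violations.append(f"C1: |selected| = {len(result.selected)} != P = {P}")
    if result.terminal not in result.selected:
        violations.append(f"C3: terminal {result.terminal} not in selected set")
    out_minus_in = np.zeros(n)
    into_T = 0.0
    for (i, j), val in result.flow.items():
        if val < -_TOL:
            violations.append(f"negativity: flow on ({i},{j}) is {val}")
        out_minus_in[i] += val
        if j == "T":
            into_T += val
            if i != result.terminal and val > _TOL:
                violations.append(f"C6: non-terminal node {i} sends {val} into T")
            if val > network.big_M + _TOL:
                violations.append(f"C6: flow into T from {i} exceeds big_M")
            if val > k[i] + _TOL:
                violations.append(f"C7: flow into T from {i} exceeds k_i = {k[i]}")
        elif j != "D":
            out_minus_in[j] -= val
            if val > network.U[i, j] + _TOL:
                violations.append(f"C5: flow on ({i},{j}) exceeds capacity U = {network.U[i, j]}")
            if (i not in result.selected or j not in result.selected) and val > _TOL:
                violations.append(f"C5: flow on arc ({i},{j}) with an unselected endpoint")
    for i in range(n):
        if abs(out_minus_in[i] - network.b[i]) > _TOL:
            violations.append(
                f"C4: balance at node {i} is {out_minus_in[i]:.8f}, supply {network.b[i]:.8f}")
    if abs(into_T - result.objective) > _TOL:
        violations.append("objective does not equal total flow into T")
    return violations


def exhaustive_oracle(network: MITransferNetwork, P: int,
                      cap: int = 20_000) -> SelectionResult:
    """Global optimum by enumerating every P-subset and terminal.

    For each subset S and terminal t in S, solves a plain max-flow problem
    on the induced graph (super-source arcs of capacity b_j, feature arcs of
    capacity U, terminal arc of capacity min(k_t, big_M)) with networkx, and
    returns the best. Ties go to the lexicographically smallest subset, then
    the smallest terminal index.
    """
    n = network.n
    if not 1 <= P <= n:
        raise ValueError(f"P must lie in [1, {n}], got {P}")
    n_subsets = math.comb(n, P)
    if n_subsets > cap:
        raise OracleCapExceededError(
            f"C({n},{P}) = {n_subsets} exceeds cap {cap}; shrink n or P")
    k = compute_upper_bounds(network, P).k
    best_val, best = -1.0, None
    for S in itertools.combinations(range(n), P):
        G = nx.DiGraph()
        for j in S:
            G.add_edge("src", j, capacity=float(network.b[j]))
        for a, bnode in itertools.combinations(S, 2):
            G.add_edge(a, bnode, capacity=float(network.U[a, bnode]))
            G.add_edge(bnode, a, capacity=float(network.U[a, bnode]))
        for t in S:
            cap_t = float(min(k[t], network.big_M))
            G.add_edge(t, "sink", capacity=cap_t)
            value, flow_dict = nx.maximum_flow(G, "src", "sink")
            G.remove_edge(t, "sink")
            if value > best_val + 1e-12:
                best_val, best = value, (S, t, flow_dict)
    S, t, flow_dict = best
    flow: dict = {}
    sel = set(S)
    for i in range(n):
        used = flow_dict.get("src", {}).get(i, 0.0) if i in sel else 0.0
        leftover = float(network.b[i]) - used
        if leftover > 1e-12:
            flow[(i, "D")] = leftover
    for u, targets in flow_dict.items():
        if u == "src":
            continue
        for w, val in targets.items():
            if val > 1e-12:
                flow[(u, "T") if w == "sink" else (u, w)] = float(val)
    return SelectionResult(frozenset(S), t, flow, float(best_val), 0.0, "optimal")


def select_features(data: DatasetTable, P: int,
                    config: MILPConfig = MILPConfig()) -> tuple[SelectionResult, MITransferNetwork]:
    """End-to-end MITN-ILP: network, bounds, model, solve."""
    network = build_network(data)
    bounds = compute_upper_bounds(network, P)
    model = build_model(network, P, bounds)
    return solve(model, config), network
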