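"""Attractor analysis: exact fixed points and brute-force asynchronous attractors.

Fixed points (steady states) are found *exactly and completely* for models
of any size by constraint propagation over the Boolean rules with
branching on undetermined indicators: a steady state satisfies
``f_v(x) = x_v`` for every unclamped indicator and clamp-consistency for
clamped ones.  Full asynchronous attractors — terminal strongly connected
components of the state-transition graph (STG) — are enumerated by brute
force for models with at most 20 indicator variables and serve as the
independent oracle for both the fixed-point solver and the stochastic
engine (via exact absorption probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .engine import Protocol, UpdateWeights, run_ensemble
from .logic import And, BoolExpr, Const, LogicalModel, Not, Or, Var

__all__ = [
    "Attractor",
    "find_fixed_points",
    "find_attractors_exhaustive",
    "exact_absorption",
    "basin_fractions",
]

MAX_EXHAUSTIVE_VARS = 20


@dataclass
class Attractor:
    """A steady state or a complex attractor (terminal SCC of the STG)."""

    kind: str  # "steady_state" | "complex"
    states: tuple  # tuple of state dicts (one for steady states)
    levels: dict  # node -> level (steady) or node -> sorted tuple of levels

    @property
    def is_steady(self) -> bool:
        return self.kind == "steady_state"

    def level_key(self):
        return tuple(
            (lvl,) if isinstance(lvl, int) else tuple(lvl) for lvl in self.levels.values()
        )


def _effective_rules(model: LogicalModel, clamps):
    """Apply time-invariant clamps: returns (rules dict, pinned dict).

    ``pinned`` maps indicator -> forced Boolean value (set_level pins the
    whole level pattern; cap_level pins indicators at/above the bound OFF).
    rule_override swaps the rule.  Time-varying (efficacy) clamps are
    rejected.
    """
    rules = dict(model.rules)
    pinned = {}
    for clamp in clamps:
        if clamp.kind == "efficacy":
            raise ValueError("attractor analysis requires time-invariant clamps")
        if clamp.kind == "rule_override":
            rules[clamp.node] = clamp.expr
        else:
            for ind, val in clamp.pin_pattern(model):
                pinned[ind] = bool(val)
    return rules, pinned


def _decode(model: LogicalModel, state) -> dict:
    return model.decode(state)


def find_fixed_points(model: LogicalModel, clamps=()) -> list:
    """Exact, complete enumeration of all fixed points under the clamps.

    Constraint propagation assigns every indicator whose rule value is
    determined by the partial assignment; contradictions prune the branch;
    undetermined indicators are branched on.  Output is canonically
    ordered (lexicographically on the decoded level vector).
    """
    rules, pinned = _effective_rules(model, clamps)
    names = [v for v in model.indicators]
    free = [v for v in names if v not in pinned]

    # indicators whose rules mention a variable, for targeted re-propagation
    dependents: dict = {v: [] for v in names}
    for v in free:
        for lit in rules[v].literals():
            dependents.setdefault(lit, []).append(v)

    solutions = []

    def propagate(assign, dirty):
        """Returns False on contradiction; mutates assign."""
        work = list(dirty)
        while work:
            v = work.pop()
            if v in pinned:
                continue
            val = rules[v].partial(assign)
            if val is None:
                continue
            if v in assign:
                if assign[v] != val:
                    return False
            else:
                assign[v] = val
                work.extend(dependents.get(v, ()))
                work.append(v)
        return True

    def check_full(assign):
        for v in free:
            if rules[v].evaluate(assign) != assign[v]:
                return False
        return True

    def branch(assign):
        unassigned = [v for v in free if v not in assign]
        if not unassigned:
            if check_full(assign):
                solutions.append(dict(assign))
            return
        # branch on the unassigned indicator with most dependents
        v = max(unassigned, key=lambda u: len(dependents.get(u, ())))
        for val in (False, True):
            trial = dict(assign)
            trial[v] = val
            if propagate(trial, [v] + dependents.get(v, [])):
                branch(trial)

    base = dict(pinned)
    if propagate(base, list(names)):
        branch(base)

    out = [
        Attractor(kind="steady_state", states=(s,), levels=_decode(model, s)) for s in solutions
    ]
    out.sort(key=Attractor.level_key)
    return out


# ---------------------------------------------------------------------------
# Brute-force state-transition graph
# ---------------------------------------------------------------------------


def _evaluate_vec(expr: BoolExpr, columns) -> np.ndarray:
    if isinstance(expr, Var):
        return columns[expr.name]
    if isinstance(expr, Const):
        n = len(next(iter(columns.values())))
        return np.full(n, expr.value, dtype=bool)
    if isinstance(expr, Not):
        return ~_evaluate_vec(expr.arg, columns)
    if isinstance(expr, And):
        out = _evaluate_vec(expr.args[0], columns)
        for a in expr.args[1:]:
            out = out & _evaluate_vec(a, columns)
        return out
    if isinstance(expr, Or):
        out = _evaluate_vec(expr.args[0], columns)
        for a in expr.args[1:]:
            out = out | _evaluate_vec(a, columns)
        return out
    raise TypeError(type(expr))


def _stg(model: LogicalModel, clamps):
    """Full asynchronous STG over the clamp-consistent state space.

    Returns (names, free, pinned, S, F) where S is the (N, n_free) bool
    state matrix over free indicators and F the next-value matrix.
    """
    rules, pinned = _effective_rules(model, clamps)
    names = model.indicators
    free = [v for v in names if v not in pinned]
    n = len(free)
    if n > MAX_EXHAUSTIVE_VARS:
        raise ValueError(f"state space too large ({n} free indicators > {MAX_EXHAUSTIVE_VARS})")
    N = 1 << n
    codes = np.arange(N, dtype=np.int64)
    S = np.empty((N, n), dtype=bool)
    for j in range(n):
        S[:, j] = (codes >> j) & 1  # free[j] is bit j

    columns = {v: S[:, j] for j, v in enumerate(free)}
    for v, val in pinned.items():
        columns[v] = np.full(N, val, dtype=bool)
    F = np.empty((N, n), dtype=bool)
    for j, v in enumerate(free):
        F[:, j] = _evaluate_vec(rules[v], columns)
    return names, free, pinned, S, F


def _terminal_sccs(S, F):
    """Labels of terminal SCCs of the asynchronous STG."""
    N, n = S.shape
    codes = np.arange(N, dtype=np.int64)
    rows, cols = [], []
    for j in range(n):
        moved = S[:, j] != F[:, j]
        rows.append(codes[moved])
        cols.append(codes[moved] ^ (1 << j))
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    adj = sp.coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(N, N)).tocsr()
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    terminal = np.ones(n_comp, dtype=bool)
    cross = labels[rows] != labels[cols]
    terminal[labels[rows[cross]]] = False
    return labels, terminal, rows, cols


def _state_dict(model, names, free, pinned, bits):
    state = dict(pinned)
    for j, v in enumerate(free):
        state[v] = bool(bits[j])
    return {v: state[v] for v in names}


def find_attractors_exhaustive(model: LogicalModel, clamps=()) -> list:
    """All asynchronous attractors (terminal SCCs) by brute force (<= 20 vars)."""
    names, free, pinned, S, F = _stg(model, clamps)
    labels, terminal, _, _ = _terminal_sccs(S, F)

    out = []
    for comp in np.flatnonzero(terminal):
        members = np.flatnonzero(labels == comp)
        states = tuple(_state_dict(model, names, free, pinned, S[m]) for m in members)
        if len(states) == 1:
            out.append(
                Attractor(kind="steady_state", states=states, levels=_decode(model, states[0]))
            )
        else:
            level_sets: dict = {}
            for s in states:
                for node, lvl in _decode(model, s).items():
                    level_sets.setdefault(node, set()).add(lvl)
            levels = {node: tuple(sorted(v)) for node, v in level_sets.items()}
            out.append(Attractor(kind="complex", states=states, levels=levels))
    out.sort(key=Attractor.level_key)
    return out


def exact_absorption(model: LogicalModel, clamps, initial_states, weights=None):
    """Exact absorption probabilities into each attractor (oracle).

    ``initial_states`` is a list of (state, probability).  Builds the
    weighted Markov chain of the general-asynchronous dynamics on the
    full state space and solves the absorption linear system.  Returns
    (attractors, probs) with probs summing to 1 (finite chains absorb).
    """
    weights = UpdateWeights.from_model(model) if weights is None else weights
    names, free, pinned, S, F = _stg(model, clamps)
    labels, terminal, _, _ = _terminal_sccs(S, F)
    N, n = S.shape
    codes = np.arange(N, dtype=np.int64)

    w_all = np.array([weights.weights[v] for v in names], dtype=float)
    total_w = w_all.sum()
    p_free = np.array([weights.weights[v] for v in free], dtype=float) / total_w

    rows, cols, vals = [codes], [codes], [np.zeros(N)]
    self_p = np.full(N, 1.0 - p_free.sum())  # pinned / no-op selection mass
    for j in range(n):
        moved = S[:, j] != F[:, j]
        tgt = codes ^ (1 << j)
        rows.append(codes[moved])
        cols.append(tgt[moved])
        vals.append(np.full(moved.sum(), p_free[j]))
        self_p[~moved] += p_free[j]
    vals[0] = self_p
    P = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    ).tocsr()

    term_labels = np.flatnonzero(terminal)
    in_terminal = terminal[labels]
    transient = np.flatnonzero(~in_terminal)
    # h_k(s) = P(absorb in terminal SCC k | start s)
    H = np.zeros((N, len(term_labels)))
    for k, comp in enumerate(term_labels):
        H[labels == comp, k] = 1.0
    if transient.size:
        Q = P[transient][:, transient]
        R = P[transient][:, np.flatnonzero(in_terminal)]
        rhs = R @ H[np.flatnonzero(in_terminal)]
        sol = sp.linalg.spsolve(sp.eye(transient.size, format="csc") - Q.tocsc(), rhs)
        H[transient] = np.atleast_2d(sol.reshape(transient.size, len(term_labels)))

    # initial states are encoded over free indicators only: pinned values
    # are overridden, matching the engine's onset-0 enforcement
    free_index = {v: j for j, v in enumerate(free)}
    probs = np.zeros(len(term_labels))
    for state, p in initial_states:
        code = 0
        for v, j in free_index.items():
            if state[v]:
                code |= 1 << j
        probs += p * H[code]
    probs = np.clip(probs, 0.0, 1.0)  # scrub linear-solver round-off

    attractors = []
    for comp in term_labels:
        members = np.flatnonzero(labels == comp)
        states = tuple(_state_dict(model, names, free, pinned, S[m]) for m in members)
        if len(states) == 1:
            attractors.append(
                Attractor(kind="steady_state", states=states, levels=_decode(model, states[0]))
            )
        else:
            level_sets: dict = {}
            for s in states:
                for node, lvl in _decode(model, s).items():
                    level_sets.setdefault(node, set()).add(lvl)
            attractors.append(
                Attractor(
                    kind="complex",
                    states=states,
                    levels={node: tuple(sorted(v)) for node, v in level_sets.items()},
                )
            )
    idx = sorted(range(len(attractors)), key=lambda i: attractors[i].level_key())
    return [attractors[i] for i in idx], probs[idx]


def basin_fractions(
    model: LogicalModel,
    clamps,
    initial_states,
    attractors,
    replicates: int = 2000,
    horizon: float = 50.0,
    seed: int = 0,
) -> dict:
    """Monte-Carlo absorption-fraction estimates for precomputed attractors.

    Returns {attractor index -> fraction} plus ``"unabsorbed"`` for final
    states matching no attractor; fractions sum to 1.
    """
    protocol = Protocol(
        initial_states=initial_states,
        clamps=list(clamps),
        horizon=horizon,
        grid=np.array([horizon]),
        replicates=replicates,
        seed=seed,
    )
    tc = run_ensemble(model, protocol)
    names = tc.variables
    lookup = {}
    for i, att in enumerate(attractors):
        for s in att.states:
            lookup[tuple(1 if s[v] else 0 for v in names)] = i

    counts: dict = {i: 0 for i in range(len(attractors))}
    counts["unabsorbed"] = 0
    for row in tc.final_states:
        counts[lookup.get(tuple(int(x) for x in row), "unabsorbed")] += 1
    return {k: v / replicates for k, v in counts.items()}
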