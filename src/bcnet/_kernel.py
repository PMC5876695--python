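"""JIT-compiled general-asynchronous ensemble kernel.

Rules are compiled to a flat reverse-Polish byte code (one stack machine
program per indicator variable) so that the micro-step loop — select one
indicator with probability proportional to its kinetic weight, evaluate
its rule, enforce clamps — runs at machine speed over thousands of
replicates.  The Python reference semantics live in
:func:`bcnet.engine.ga_step`; the two paths are cross-checked in the test
suite against exact absorption probabilities on the state-transition
graph.

Opcodes: 0 PUSH_VAR(idx), 1 PUSH_CONST(0/1), 2 NOT, 3 AND, 4 OR.
Clamp kinds: 0 pin pattern (set_level / drug ON), 1 cap (force
indicators OFF), 2 partial-efficacy pin (drops the pinned node to level 0
with probability ``p_off`` per micro-step), 3 rule override (alternate
byte-code range for one indicator).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .logic import And, Const, Not, Or, Var

OP_VAR, OP_CONST, OP_NOT, OP_AND, OP_OR = 0, 1, 2, 3, 4
K_PIN, K_CAP, K_EFF, K_OVERRIDE = 0, 1, 2, 3


def compile_expr(expr, var_index, code):
    """Append RPN byte code for ``expr`` to ``code`` (list of int pairs)."""
    if isinstance(expr, Var):
        code.append(OP_VAR)
        code.append(var_index[expr.name])
    elif isinstance(expr, Const):
        code.append(OP_CONST)
        code.append(1 if expr.value else 0)
    elif isinstance(expr, Not):
        compile_expr(expr.arg, var_index, code)
        code.append(OP_NOT)
        code.append(0)
    elif isinstance(expr, (And, Or)):
        op = OP_AND if isinstance(expr, And) else OP_OR
        compile_expr(expr.args[0], var_index, code)
        for arg in expr.args[1:]:
            compile_expr(arg, var_index, code)
            code.append(op)
            code.append(0)
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot compile {type(expr).__name__}")


def compile_rules(exprs, var_index):
    """Compile a list of expressions; returns (code, starts, ends) arrays."""
    code: list[int] = []
    starts = np.empty(len(exprs), dtype=np.int64)
    ends = np.empty(len(exprs), dtype=np.int64)
    for i, expr in enumerate(exprs):
        starts[i] = len(code)
        compile_expr(expr, var_index, code)
        ends[i] = len(code)
    return np.asarray(code, dtype=np.int64), starts, ends


@njit(cache=True, inline="always")
def _eval_rpn(code, start, end, state, stack):
    sp = 0
    i = start
    while i < end:
        op = code[i]
        arg = code[i + 1]
        if op == OP_VAR:
            stack[sp] = state[arg]
            sp += 1
        elif op == OP_CONST:
            stack[sp] = arg
            sp += 1
        elif op == OP_NOT:
            stack[sp - 1] = 1 - stack[sp - 1]
        elif op == OP_AND:
            sp -= 1
            if stack[sp] == 0:
                stack[sp - 1] = 0
        else:  # OP_OR
            sp -= 1
            if stack[sp] == 1:
                stack[sp - 1] = 1
        i += 2
    return stack[0]


@njit(cache=True)
def run_kernel(
    code,
    starts,
    ends,
    cum_w,
    init_states,
    seeds,
    micro_total,
    record_micro,
    clamp_kind,
    clamp_on,
    clamp_off,
    clamp_poff,
    clamp_ptr,
    clamp_vars,
    clamp_vals,
    ovr_var,
    ovr_start,
    ovr_end,
    node_ptr,
    node_vars,
):
    """Simulate all replicates; accumulate activities and level occupancies.

    Returns (act_sum, occ_count, final_states):
      act_sum   (n_grid, n_var)  float64 — sum of indicator states
      occ_count (n_grid, n_node, max_level+1) float64 — decoded-level counts
      final_states (n_rep, n_var) uint8
    """
    n_rep, n_var = init_states.shape
    n_grid = record_micro.shape[0]
    n_node = node_ptr.shape[0] - 1
    max_levels = 0
    for n in range(n_node):
        width = node_ptr[n + 1] - node_ptr[n] + 1
        if width > max_levels:
            max_levels = width
    n_clamp = clamp_kind.shape[0]

    act_sum = np.zeros((n_grid, n_var), dtype=np.float64)
    occ_count = np.zeros((n_grid, n_node, max_levels), dtype=np.float64)
    final_states = np.empty((n_rep, n_var), dtype=np.uint8)
    stack = np.empty(64, dtype=np.uint8)
    state = np.empty(n_var, dtype=np.uint8)

    for r in range(n_rep):
        np.random.seed(seeds[r])
        for v in range(n_var):
            state[v] = init_states[r, v]
        g = 0

        for t in range(micro_total + 1):
            # enforce deterministic pins active during micro-step t (also
            # covers onset enforcement before the first affected update)
            for c in range(n_clamp):
                if clamp_on[c] <= t < clamp_off[c]:
                    k = clamp_kind[c]
                    if k == K_PIN or k == K_CAP:
                        for j in range(clamp_ptr[c], clamp_ptr[c + 1]):
                            state[clamp_vars[j]] = clamp_vals[j]

            if t == micro_total:
                break

            # general-asynchronous update: one indicator variable
            u = np.random.random()
            v = np.searchsorted(cum_w, u)
            if v >= n_var:
                v = n_var - 1
            s = starts[v]
            e = ends[v]
            for c in range(n_clamp):
                if clamp_kind[c] == K_OVERRIDE and ovr_var[c] == v and clamp_on[c] <= t < clamp_off[c]:
                    s = ovr_start[c]
                    e = ovr_end[c]
            state[v] = _eval_rpn(code, s, e, state, stack)

            # re-enforce pins (the update may have touched a pinned
            # indicator) and apply partial-efficacy clamps
            for c in range(n_clamp):
                if clamp_on[c] <= t < clamp_off[c]:
                    k = clamp_kind[c]
                    if k == K_PIN or k == K_CAP:
                        for j in range(clamp_ptr[c], clamp_ptr[c + 1]):
                            state[clamp_vars[j]] = clamp_vals[j]
                    elif k == K_EFF:
                        if np.random.random() < clamp_poff[c]:
                            for j in range(clamp_ptr[c], clamp_ptr[c + 1]):
                                state[clamp_vars[j]] = 0
                        else:
                            for j in range(clamp_ptr[c], clamp_ptr[c + 1]):
                                state[clamp_vars[j]] = clamp_vals[j]

            # record the state at the last micro-step not exceeding each
            # grid point (grid points were converted to micro indices)
            while g < n_grid and record_micro[g] == t + 1:
                for v2 in range(n_var):
                    act_sum[g, v2] += state[v2]
                for n in range(n_node):
                    lvl = 0
                    for j in range(node_ptr[n], node_ptr[n + 1]):
                        if state[node_vars[j]] == 1:
                            lvl = j - node_ptr[n] + 1
                    occ_count[g, n, lvl] += 1.0
                g += 1

        # grid points at micro index 0 (initial state) were skipped by the
        # in-loop recorder; handle them here for completeness
        for v in range(n_var):
            final_states[r, v] = state[v]

    return act_sum, occ_count, final_states


@njit(cache=True)
def record_initial(init_states, clamp_kind, clamp_on, clamp_ptr, clamp_vars, clamp_vals, node_ptr, node_vars):
    """Activities/occupancies of the initial ensemble after onset-0 pins."""
    n_rep, n_var = init_states.shape
    n_node = node_ptr.shape[0] - 1
    max_levels = 0
    for n in range(n_node):
        width = node_ptr[n + 1] - node_ptr[n] + 1
        if width > max_levels:
            max_levels = width
    act = np.zeros(n_var, dtype=np.float64)
    occ = np.zeros((n_node, max_levels), dtype=np.float64)
    state = np.empty(n_var, dtype=np.uint8)
    for r in range(n_rep):
        for v in range(n_var):
            state[v] = init_states[r, v]
        for c in range(clamp_kind.shape[0]):
            if clamp_on[c] <= 0 and (clamp_kind[c] == K_PIN or clamp_kind[c] == K_CAP):
                for j in range(clamp_ptr[c], clamp_ptr[c + 1]):
                    state[clamp_vars[j]] = clamp_vals[j]
        for v in range(n_var):
            act[v] += state[v]
        for n in range(n_node):
            lvl = 0
            for j in range(node_ptr[n], node_ptr[n + 1]):
                if state[node_vars[j]] == 1:
                    lvl = j - node_ptr[n] + 1
            occ[n, lvl] += 1.0
    return act, occ
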