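"""General-asynchronous simulation of multi-level logical models.

One indicator variable is updated per micro-step, selected with
probability proportional to its kinetic weight (fast signaling
indicators get 5x the weight of slow transcriptional ones by default).
Time is reported on a scaled axis whose unit is the average time needed
to update one slow indicator: ``scaled_time = micro_steps * p_slow``
where ``p_slow`` is the selection probability of a single slow variable.

Interventions are :class:`Clamp` objects with scaled onset/offset times:

``set_level``
    pins a node at a level (indicators k<=level ON, k>level OFF) — the
    semantics of setting a drug node ON at a given time;
``cap_level``
    pins the indicators at or above a bound OFF, leaving lower levels
    free (``pRb < 2``-style interventions);
``rule_override``
    swaps one indicator's rule, so the state changes only when that
    indicator is next selected (an activating mutation, ``f_RAS = ON``);
``efficacy``
    a partially effective set_level: each micro-step the pinned node is
    dropped to level 0 with probability ``p_off`` (a 90%-effective drug
    target has ``p_off = 0.10``).

Single trajectories run in pure Python (:func:`run_trajectory`);
ensembles run through the JIT-compiled kernel (:func:`run_ensemble`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .logic import And, BoolExpr, LogicalModel, Not, NodeSpec, Or, Var, indicator_name

__all__ = [
    "DEFAULT_FAST_SLOW_RATIO",
    "UpdateWeights",
    "Clamp",
    "Protocol",
    "Trajectory",
    "EnsembleTimecourse",
    "scaled_time",
    "micro_steps_for",
    "ga_step",
    "run_trajectory",
    "run_ensemble",
    "add_inhibitor",
]

DEFAULT_FAST_SLOW_RATIO = 5.0


@dataclass
class UpdateWeights:
    """Per-indicator selection weights derived from node kinetic classes.

    ``unit_weight`` is the weight of the slow class when the model has
    slow indicators; it defines the scaled-time unit.
    """

    weights: dict
    unit_weight: float | None = None

    @classmethod
    def from_model(
        cls, model: LogicalModel, fast: float = DEFAULT_FAST_SLOW_RATIO, slow: float = 1.0
    ) -> "UpdateWeights":
        w = {}
        has_slow = False
        for spec in model.nodes:
            wv = fast if spec.update_class == "fast" else slow
            has_slow = has_slow or spec.update_class == "slow"
            for ind in spec.indicators:
                w[ind] = float(wv)
        return cls(w, unit_weight=float(slow) if has_slow else None)

    @property
    def total(self) -> float:
        return sum(self.weights.values())

    def probability(self, indicator: str) -> float:
        return self.weights[indicator] / self.total

    @property
    def p_slow(self) -> float:
        """Selection probability of one slow-class indicator (the time unit).

        If no slow indicator exists, the slowest class present defines the
        unit (with a warning).
        """
        if not self.weights:
            raise ValueError("empty weight map")
        if self.unit_weight is not None:
            return self.unit_weight / self.total
        warnings.warn("no slow variables; slowest class present defines the time unit")
        return min(self.weights.values()) / self.total


def scaled_time(micro_steps: int, weights: UpdateWeights) -> float:
    """Scaled time elapsed after ``micro_steps`` single-variable updates."""
    return micro_steps * weights.p_slow

def micro_steps_for(t: float, weights: UpdateWeights) -> int:
    """Inverse of :func:`scaled_time`, rounding up to the next micro-step."""
    return int(math.ceil(t / weights.p_slow - 1e-9))


@dataclass
class Clamp:
    """A timed intervention on a node (or, for rule_override, an indicator)."""

    kind: str
    node: str
    level: int | None = None
    onset: float = 0.0
    offset: float | None = None
    p_off: float | None = None
    expr: BoolExpr | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("set_level", "cap_level", "rule_override", "efficacy"):
            raise ValueError(f"unknown clamp kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("clamp onset must be >= 0")
        if self.kind == "efficacy":
            if self.p_off is None or not 0.0 <= self.p_off < 1.0:
                raise ValueError("efficacy clamp needs p_off in [0, 1)")
        if self.kind == "rule_override" and self.expr is None:
            raise ValueError("rule_override clamp needs an expression")

    def pin_pattern(self, model: LogicalModel) -> list:
        """(indicator, value) pairs this clamp pins, for set/cap/efficacy."""
        spec = model.node(self.node)
        if self.kind in ("set_level", "efficacy"):
            lvl = int(self.level)
            if not 0 <= lvl < spec.n_levels:
                raise ValueError(f"level {lvl} out of range for {self.node}")
            return [(indicator_name(spec.name, k), k <= lvl) for k in range(1, spec.n_levels)]
        if self.kind == "cap_level":
            bound = int(self.level)
            if not 1 <= bound < spec.n_levels:
                raise ValueError(f"cap bound {bound} out of range for {self.node}")
            return [(indicator_name(spec.name, k), False) for k in range(bound, spec.n_levels)]
        return []

    def label(self) -> str:
        if self.kind == "set_level":
            return f"{self.node} = {self.level}"
        if self.kind == "cap_level":
            return f"{self.node} < {self.level}"
        if self.kind == "efficacy":
            return f"{self.node} = {self.level} (p_off={self.p_off})"
        return f"f_{self.node} := {self.expr.to_text()}"


@dataclass
class Protocol:
    """Initial ensemble, clamps, horizon, sampling grid and replicates."""

    initial_states: list  # list of (complete indicator state dict, probability)
    clamps: list = field(default_factory=list)
    horizon: float = 75.0
    grid: np.ndarray | None = None
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.initial_states)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"initial-state probabilities sum to {total}, not 1")
        if self.grid is None:
            self.grid = np.arange(0.0, self.horizon + 1e-9, 1.0)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > self.horizon + 1e-9):
            raise ValueError("sampling grid must lie within [0, horizon]")

    def with_clamps(self, extra, **overrides) -> "Protocol":
        kw = dict(
            initial_states=self.initial_states,
            clamps=list(self.clamps) + list(extra),
            horizon=self.horizon,
            grid=self.grid,
            replicates=self.replicates,
            seed=self.seed,
        )
        kw.update(overrides)
        return Protocol(**kw)


@dataclass
class Trajectory:
    """A single stochastic run: states sampled at micro-step resolution."""

    times: list
    states: list
    model: LogicalModel

    @property
    def final_state(self) -> dict:
        return self.states[-1]

    def decoded_final(self) -> dict:
        return self.model.decode(self.final_state)


def _active(clamp: Clamp, t_scaled: float) -> bool:
    if t_scaled < clamp.onset - 1e-12:
        return False
    return clamp.offset is None or t_scaled < clamp.offset - 1e-12


def ga_step(state, model: LogicalModel, weights: UpdateWeights, clamps=(), rng=None):
    """One general-asynchronous micro-step (pure-Python reference).

    Exactly one indicator is selected with probability proportional to its
    weight and set to the value of its rule on the *previous* state; all
    other indicators are copied.  Active clamps are then enforced.
    ``clamps`` is the set of currently active clamps (time windows are the
    caller's concern).
    """
    rng = np.random.default_rng() if rng is None else rng
    names = model.indicators
    w = np.array([weights.weights[v] for v in names])
    v = names[rng.choice(len(names), p=w / w.sum())]

    rule = model.rules[v]
    for clamp in clamps:
        if clamp.kind == "rule_override" and clamp.node == v:
            rule = clamp.expr
    new = dict(state)
    new[v] = bool(rule.evaluate(state))

    for clamp in clamps:
        if clamp.kind in ("set_level", "cap_level"):
            for ind, val in clamp.pin_pattern(model):
                new[ind] = val
        elif clamp.kind == "efficacy":
            drop = rng.random() < clamp.p_off
            for ind, val in clamp.pin_pattern(model):
                new[ind] = False if drop else val
    return new


def _sample_initial(protocol: Protocol, model: LogicalModel, rng) -> dict:
    probs = np.array([p for _, p in protocol.initial_states])
    idx = rng.choice(len(probs), p=probs / probs.sum())
    state = dict(protocol.initial_states[idx][0])
    missing = [v for v in model.indicators if v not in state]
    if missing:
        raise ValueError(f"initial state missing indicators: {missing[:3]}...")
    return state


def run_trajectory(model: LogicalModel, protocol: Protocol, seed=None) -> Trajectory:
    """Run one trajectory to the horizon (pure Python; small models).

    Clamps activate and deactivate at their scaled onset/offset times;
    deterministic pins are enforced on the state the moment they become
    active.  Reproducible given ``seed`` (defaults to ``protocol.seed``).
    """
    weights = UpdateWeights.from_model(model)
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    p_slow = weights.p_slow
    n_micro = micro_steps_for(protocol.horizon, weights)

    state = _sample_initial(protocol, model, rng)
    prev_active: set = set()
    times = [0.0]
    states = []

    def enforce_new_pins(t_scaled):
        nonlocal state
        for i, clamp in enumerate(protocol.clamps):
            if _active(clamp, t_scaled) and i not in prev_active:
                prev_active.add(i)
                if clamp.kind in ("set_level", "cap_level"):
                    state = dict(state)
                    for ind, val in clamp.pin_pattern(model):
                        state[ind] = val
            elif not _active(clamp, t_scaled) and i in prev_active:
                prev_active.discard(i)

    enforce_new_pins(0.0)
    states.append(state)
    for t in range(n_micro):
        t_scaled = t * p_slow
        enforce_new_pins(t_scaled)
        active = [c for c in protocol.clamps if _active(c, t_scaled)]
        state = ga_step(state, model, weights, active, rng)
        times.append((t + 1) * p_slow)
        states.append(state)
    return Trajectory(times=times, states=states, model=model)


@dataclass
class EnsembleTimecourse:
    """Per-variable activities and per-node level occupancies on a grid."""

    grid: np.ndarray
    variables: list
    activities: np.ndarray  # (n_grid, n_var) in [0, 1]
    node_names: list
    node_levels: list  # n_levels per node
    occupancy: np.ndarray  # (n_grid, n_node, max_levels) fractions
    replicates: int
    seed: int
    final_states: np.ndarray  # (n_rep, n_var) uint8
    model: LogicalModel

    def activity(self, variable: str) -> np.ndarray:
        return self.activities[:, self.variables.index(variable)]

    def occupancy_of(self, node: str) -> np.ndarray:
        i = self.node_names.index(node)
        return self.occupancy[:, i, : self.node_levels[i]]

    def final_occupancy(self, node: str) -> dict:
        occ = self.occupancy_of(node)[-1]
        return {lvl: float(occ[lvl]) for lvl in range(occ.shape[0])}

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (time, variable, activity) table."""
        n_grid, n_var = self.activities.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.grid, n_var),
                "variable": np.tile(np.asarray(self.variables, dtype=object), n_grid),
                "activity": self.activities.ravel(),
            }
        )


def _clamp_arrays(model, protocol, weights, var_index, code, starts, ends):
    """Compile protocol clamps into the kernel's flat arrays."""
    kinds, ons, offs, poffs, ptr, cvars, cvals = [], [], [], [], [0], [], []
    ovr_var, ovr_start, ovr_end = [], [], []
    code = list(code)
    n_micro_big = 2**62

    for clamp in protocol.clamps:
        on = micro_steps_for(clamp.onset, weights)
        off = n_micro_big if clamp.offset is None else micro_steps_for(clamp.offset, weights)
        if clamp.kind == "rule_override":
            kinds.append(_kernel.K_OVERRIDE)
            ovr_var.append(var_index[clamp.node])
            ovr_start.append(len(code))
            _kernel.compile_expr(clamp.expr, var_index, code)
            ovr_end.append(len(code))
        else:
            kinds.append(
                {"set_level": _kernel.K_PIN, "cap_level": _kernel.K_CAP, "efficacy": _kernel.K_EFF}[
                    clamp.kind
                ]
            )
            ovr_var.append(-1)
            ovr_start.append(0)
            ovr_end.append(0)
            for ind, val in clamp.pin_pattern(model):
                cvars.append(var_index[ind])
                cvals.append(1 if val else 0)
        ons.append(on)
        offs.append(off)
        poffs.append(clamp.p_off or 0.0)
        ptr.append(len(cvars))

    return (
        np.asarray(code, dtype=np.int64),
        np.asarray(kinds, dtype=np.int64),
        np.asarray(ons, dtype=np.int64),
        np.asarray(offs, dtype=np.int64),
        np.asarray(poffs, dtype=np.float64),
        np.asarray(ptr, dtype=np.int64),
        np.asarray(cvars, dtype=np.int64),
        np.asarray(cvals, dtype=np.uint8),
        np.asarray(ovr_var, dtype=np.int64),
        np.asarray(ovr_start, dtype=np.int64),
        np.asarray(ovr_end, dtype=np.int64),
    )


def run_ensemble(
    model: LogicalModel, protocol: Protocol, weights: UpdateWeights | None = None
) -> EnsembleTimecourse:
    """Run ``protocol.replicates`` independent trajectories (JIT kernel).

    Replicate r uses a deterministic child seed of ``protocol.seed``, so
    results are bit-reproducible per seed.
    """
    weights = UpdateWeights.from_model(model) if weights is None else weights
    names = model.indicators
    var_index = {v: i for i, v in enumerate(names)}
    exprs = [model.rules[v] for v in names]
    code, starts, ends = _kernel.compile_rules(exprs, var_index)

    w = np.array([weights.weights[v] for v in names], dtype=np.float64)
    cum_w = np.cumsum(w / w.sum())
    p_slow = weights.p_slow
    n_micro = micro_steps_for(protocol.horizon, weights)

    # initial ensemble
    rng = np.random.default_rng(protocol.seed)
    probs = np.array([p for _, p in protocol.initial_states], dtype=float)
    choice = rng.choice(len(probs), size=protocol.replicates, p=probs / probs.sum())
    init = np.empty((protocol.replicates, len(names)), dtype=np.uint8)
    for i, (state, _) in enumerate(protocol.initial_states):
        row = np.array([1 if state[v] else 0 for v in names], dtype=np.uint8)
        init[choice == i] = row
    seeds = np.random.SeedSequence(protocol.seed).generate_state(
        protocol.replicates, dtype=np.uint32
    ).astype(np.int64)

    # node -> indicator index table for level decoding
    node_ptr = [0]
    node_vars = []
    for spec in model.nodes:
        node_vars.extend(var_index[ind] for ind in spec.indicators)
        node_ptr.append(len(node_vars))
    node_ptr = np.asarray(node_ptr, dtype=np.int64)
    node_vars = np.asarray(node_vars, dtype=np.int64)

    (code, kinds, ons, offs, poffs, ptr, cvars, cvals, ovr_var, ovr_start, ovr_end) = _clamp_arrays(
        model, protocol, weights, var_index, code, starts, ends
    )

    record_micro_all = np.array(
        [min(int(np.floor(g / p_slow + 1e-9)), n_micro) for g in protocol.grid], dtype=np.int64
    )
    positive = record_micro_all > 0
    act_sum, occ_count, final_states = _kernel.run_kernel(
        code,
        starts,
        ends,
        cum_w,
        init,
        seeds,
        n_micro,
        record_micro_all[positive],
        kinds,
        ons,
        offs,
        poffs,
        ptr,
        cvars,
        cvals,
        ovr_var,
        ovr_start,
        ovr_end,
        node_ptr,
        node_vars,
    )

    n_grid = protocol.grid.size
    max_levels = max(spec.n_levels for spec in model.nodes)
    activities = np.zeros((n_grid, len(names)))
    occupancy = np.zeros((n_grid, len(model.nodes), max_levels))
    if (~positive).any():
        act0, occ0 = _kernel.record_initial(init, kinds, ons, ptr, cvars, cvals, node_ptr, node_vars)
        activities[~positive] = act0 / protocol.replicates
        occupancy[~positive, :, : occ0.shape[1]] = occ0 / protocol.replicates
    activities[positive] = act_sum / protocol.replicates
    occupancy[positive, :, : occ_count.shape[2]] = occ_count / protocol.replicates

    return EnsembleTimecourse(
        grid=protocol.grid,
        variables=list(names),
        activities=activities,
        node_names=model.node_names,
        node_levels=[spec.n_levels for spec in model.nodes],
        occupancy=occupancy,
        replicates=protocol.replicates,
        seed=protocol.seed,
        final_states=final_states,
        model=model,
    )


def add_inhibitor(model: LogicalModel, drug: str, targets) -> LogicalModel:
    """Add a drug source node and conjoin ``and not drug`` to target rules.

    ``targets`` is a list of (indicator, guard) pairs; a non-None guard g
    yields ``and (not drug or g)`` — the escape pattern by which a high
    substrate level overcomes the inhibitor.  The drug node defaults to
    OFF and is self-sustaining; turn it on with a set_level clamp.
    """
    if any(spec.name == drug for spec in model.nodes):
        raise ValueError(f"name collision: node {drug} exists")
    out = model.copy()
    out.nodes.append(NodeSpec(name=drug, n_levels=2, update_class="fast", pathway="drug", is_source=True))
    out.rules[drug] = Var(drug)
    for target, guard in targets:
        if target not in out.rules:
            raise KeyError(f"no indicator named {target!r}")
        inhibition = Not(Var(drug)) if guard is None else Or(Not(Var(drug)), guard)
        out.rules[target] = And(out.rules[target], inhibition)
    return out
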