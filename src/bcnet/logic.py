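"""Core representation of multi-level logical models.

A model is a set of named nodes, each with ``n_levels`` discrete activity
levels (0 .. n_levels-1).  Following the standard Boolean expansion of
multi-level networks, a node with L levels is represented internally by
L-1 Boolean *indicator variables*: the bare node name stands for
"level >= 1", and ``<name>_k`` stands for "level >= k" for k = 2..L-1.
Every indicator has exactly one Boolean regulatory rule over the
indicators of the model, built from AND / OR / NOT and the constants
0 / 1.  Indicators are updated independently and are *not* forced to
satisfy the staircase property (``X_2 => X``); decoding a state back to
a per-node level uses the max-index convention (see :func:`decode_level`).

Dynamics (general-asynchronous updating) live in :mod:`bcnet.engine`;
parsing and writing of the text rule-file dialect live in
:mod:`bcnet.ruleformat`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "IDENT_RE",
    "NodeSpec",
    "BoolExpr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "LogicalModel",
    "decode_level",
    "evaluate_rule",
    "apply_context",
    "validate_model",
    "indicator_name",
    "truth_table",
]

#: Identifiers are case-sensitive; ``/`` is allowed (e.g. ``MEK/ERK``).
#: The ``_<digits>`` suffix is reserved for level indicators.
IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_/]*")


def indicator_name(node: str, level: int) -> str:
    """Name of the Boolean indicator for ``node`` at level >= ``level``."""
    if level < 1:
        raise ValueError("indicator levels start at 1")
    return node if level == 1 else f"{node}_{level}"


@dataclass(frozen=True)
class NodeSpec:
    """Identity, level count and kinetic class of one network node.

    ``update_class`` distinguishes fast (signaling) from slow
    (transcriptional/translational) events; the engine gives fast
    indicators a 5x higher selection probability by default.
    """

    name: str
    n_levels: int = 2
    update_class: str = "fast"
    pathway: str = ""
    is_source: bool = False

    def __post_init__(self) -> None:
        if not IDENT_RE.fullmatch(self.name):
            raise ValueError(f"invalid node name {self.name!r}")
        if self.n_levels < 2:
            raise ValueError(f"node {self.name}: n_levels must be >= 2")
        if self.update_class not in ("fast", "slow"):
            raise ValueError(f"node {self.name}: bad update class {self.update_class!r}")

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(indicator_name(self.name, k) for k in range(1, self.n_levels))


# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------


class BoolExpr:
    """Base class for Boolean expression trees over indicator variables."""

    __slots__ = ()

    def evaluate(self, state) -> bool:
        """Evaluate on a complete assignment (mapping name -> bool)."""
        raise NotImplementedError

    def partial(self, state):
        """Three-valued evaluation: returns True/False/None on a partial
        assignment (mapping name -> bool for assigned names only)."""
        raise NotImplementedError

    def literals(self) -> frozenset:
        """Set of indicator names referenced by the expression."""
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    # precedence used by to_text: Or=1, And=2, Not=3, atoms=4
    _prec = 4

    def _paren(self, parent_prec: int) -> str:
        text = self.to_text()
        return f"({text})" if self._prec < parent_prec else text

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.to_text()}>"

    def __eq__(self, other) -> bool:
        return isinstance(other, BoolExpr) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def _key(self):
        raise NotImplementedError


class Var(BoolExpr):
    __slots__ = ("name",)
    _prec = 4

    def __init__(self, name: str):
        if not IDENT_RE.fullmatch(name):
            raise ValueError(f"invalid literal {name!r}")
        self.name = name

    def evaluate(self, state) -> bool:
        try:
            return bool(state[self.name])
        except KeyError:
            raise KeyError(f"literal {self.name!r} not in state") from None

    def partial(self, state):
        return None if self.name not in state else bool(state[self.name])

    def literals(self):
        return frozenset((self.name,))

    def to_text(self) -> str:
        return self.name

    def _key(self):
        return ("var", self.name)


class Const(BoolExpr):
    __slots__ = ("value",)
    _prec = 4

    def __init__(self, value: bool):
        self.value = bool(value)

    def evaluate(self, state) -> bool:
        return self.value

    def partial(self, state):
        return self.value

    def literals(self):
        return frozenset()

    def to_text(self) -> str:
        return "1" if self.value else "0"

    def _key(self):
        return ("const", self.value)


class Not(BoolExpr):
    __slots__ = ("arg",)
    _prec = 3

    def __init__(self, arg: BoolExpr):
        self.arg = arg

    def evaluate(self, state) -> bool:
        return not self.arg.evaluate(state)

    def partial(self, state):
        v = self.arg.partial(state)
        return None if v is None else not v

    def literals(self):
        return self.arg.literals()

    def to_text(self) -> str:
        return f"not {self.arg._paren(self._prec + 1)}"

    def _key(self):
        return ("not", self.arg._key())


class _NaryOp(BoolExpr):
    __slots__ = ("args",)
    _word = ""
    _absorbing = True  # value that short-circuits

    def __init__(self, *args: BoolExpr):
        if len(args) < 2:
            raise ValueError(f"{type(self).__name__} needs >= 2 arguments")
        self.args = tuple(args)

    def evaluate(self, state) -> bool:
        a = self._absorbing
        for arg in self.args:
            if arg.evaluate(state) is a:
                return a
        return not a

    def partial(self, state):
        a = self._absorbing
        saw_none = False
        for arg in self.args:
            v = arg.partial(state)
            if v is None:
                saw_none = True
            elif v is a:
                return a
        return None if saw_none else not a

    def literals(self):
        out = frozenset()
        for arg in self.args:
            out |= arg.literals()
        return out

    def to_text(self) -> str:
        return f" {self._word} ".join(arg._paren(self._prec) for arg in self.args)

    def _key(self):
        return (self._word, tuple(arg._key() for arg in self.args))


class And(_NaryOp):
    __slots__ = ()
    _prec = 2
    _word = "and"
    _absorbing = False


class Or(_NaryOp):
    __slots__ = ()
    _prec = 1
    _word = "or"
    _absorbing = True


def evaluate_rule(expr: BoolExpr, state) -> bool:
    """Standard Boolean semantics of AND/OR/NOT on a complete assignment."""
    return expr.evaluate(state)


def truth_table(expr: BoolExpr, variables=None):
    """Brute-force truth table of ``expr``.

    Returns (variables, tuple of outputs ordered by the binary count of the
    inputs, least-significant variable last).  Used as the enumeration
    oracle in tests and by the synthetic generator round-trip.
    """
    names = sorted(expr.literals()) if variables is None else list(variables)
    outs = []
    for bits in itertools.product((False, True), repeat=len(names)):
        outs.append(expr.evaluate(dict(zip(names, bits))))
    return names, tuple(outs)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class LogicalModel:
    """A multi-level logical model over Boolean indicator variables.

    ``rules`` maps every indicator name to its Boolean rule; a node with L
    levels contributes exactly L-1 indicators.
    """

    nodes: list = field(default_factory=list)
    rules: dict = field(default_factory=dict)

    # -- structure ---------------------------------------------------------

    def node(self, name: str) -> NodeSpec:
        for spec in self.nodes:
            if spec.name == name:
                return spec
        raise KeyError(f"no node named {name!r}")

    @property
    def node_names(self) -> list:
        return [spec.name for spec in self.nodes]

    @property
    def indicators(self) -> list:
        """All indicator names, in node declaration order."""
        out = []
        for spec in self.nodes:
            out.extend(spec.indicators)
        return out

    def indicator_node(self, indicator: str) -> NodeSpec:
        """The node an indicator belongs to."""
        for spec in self.nodes:
            if indicator in spec.indicators:
                return spec
        raise KeyError(f"no indicator named {indicator!r}")

    def copy(self) -> "LogicalModel":
        return LogicalModel(nodes=list(self.nodes), rules=dict(self.rules))

    def structurally_equal(self, other: "LogicalModel") -> bool:
        if [replace(n) for n in self.nodes] != [replace(n) for n in other.nodes]:
            return False
        return self.rules == other.rules

    # -- semantics ---------------------------------------------------------

    def next_value(self, indicator: str, state) -> bool:
        return self.rules[indicator].evaluate(state)

    def decode(self, state) -> dict:
        """Per-node levels of a complete indicator assignment."""
        return {spec.name: decode_level(state, spec) for spec in self.nodes}

    def encode_levels(self, levels) -> dict:
        """Staircase indicator assignment realizing per-node levels.

        Nodes missing from ``levels`` default to level 0.
        """
        state = {}
        for spec in self.nodes:
            lvl = int(levels.get(spec.name, 0))
            if not 0 <= lvl < spec.n_levels:
                raise ValueError(f"level {lvl} out of range for node {spec.name}")
            for k in range(1, spec.n_levels):
                state[indicator_name(spec.name, k)] = k <= lvl
        return state


def decode_level(state, node: NodeSpec) -> int:
    """Level of ``node`` in ``state``: max k with indicator (node, k) ON.

    For staircase-consistent states this is the ordinary multi-level state;
    for non-staircase states the max-index convention applies.
    """
    level = 0
    for k in range(1, node.n_levels):
        if state[indicator_name(node.name, k)]:
            level = k
    return level


def validate_model(model: LogicalModel) -> list:
    """Check all model invariants; returns a list of diagnostic strings.

    An empty list means the model is valid.  Diagnostics name the violated
    invariant and the offending node or rule; nothing raises.
    """
    diags = []
    seen = set()
    for spec in model.nodes:
        if spec.name in seen:
            diags.append(f"duplicate node name: {spec.name}")
        seen.add(spec.name)

    declared = set()
    for spec in model.nodes:
        declared.update(spec.indicators)

    # reserved _k suffix must not collide with another node's indicators
    for spec in model.nodes:
        m = re.fullmatch(r"(.+)_(\d+)", spec.name)
        if m and m.group(1) in seen:
            diags.append(
                f"node name {spec.name} uses the reserved _k indicator suffix of node {m.group(1)}"
            )

    for spec in model.nodes:
        for ind in spec.indicators:
            if ind not in model.rules:
                diags.append(f"missing rule for {ind}")
    for ind in model.rules:
        if ind not in declared:
            diags.append(f"rule for undeclared indicator: {ind}")

    for ind, expr in model.rules.items():
        for lit in sorted(expr.literals()):
            if lit not in declared:
                diags.append(f"rule {ind}: undeclared literal {lit}")

    for spec in model.nodes:
        if spec.is_source:
            own = set(spec.indicators)
            for ind in spec.indicators:
                expr = model.rules.get(ind)
                if expr is not None and not expr.literals() <= own:
                    diags.append(f"source node not self-contained: {spec.name} (rule {ind})")
    return diags


def apply_context(model: LogicalModel, assignments) -> LogicalModel:
    """Fix source nodes to constant levels (cell context / genotype).

    ``assignments`` maps node name -> level.  Each named node must be a
    source node; its indicator rules are replaced by constants realizing
    the level (indicator k ON iff k <= level).
    """
    out = model.copy()
    for name, level in assignments.items():
        spec = out.node(name)
        if not spec.is_source:
            raise ValueError(f"{name} is not a source node")
        level = int(level)
        if not 0 <= level < spec.n_levels:
            raise ValueError(f"level {level} out of range for node {name}")
        for k in range(1, spec.n_levels):
            out.rules[indicator_name(name, k)] = Const(k <= level)
    return out
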