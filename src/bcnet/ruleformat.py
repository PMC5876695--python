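"""Text rule-file dialect: parser and writer.

The dialect (UTF-8, ``#`` comments, one statement per line)::

    node <Name> levels=<L> class=<fast|slow> pathway=<tag> [source]
    rule <Name> = <expr>           # indicator (Name, 1)
    rule <Name>_<k> = <expr>       # indicator (Name, k), k = 2..L-1
    outcome <Name> weights=<w0>,<w1>,...,<w_{L-1}>   # optional

``<expr>`` is built from indicator identifiers, ``and``, ``or``, ``not``,
parentheses and the constants ``0`` / ``1``.  Identifiers are
case-sensitive and match ``[A-Za-z][A-Za-z0-9_/]*``; the ``_<k>`` suffix
is reserved for level indicators.  ``outcome`` lines carry the
level->weight maps used by :mod:`bcnet.outcomes`; weights must be
non-decreasing in level.

Parsing then writing then re-parsing is structurally the identity (up to
whitespace and comments), which the test suite checks on generated models.
"""

from __future__ import annotations

import re

from .logic import (
    IDENT_RE,
    And,
    BoolExpr,
    Const,
    LogicalModel,
    NodeSpec,
    Not,
    Or,
    Var,
    validate_model,
)

__all__ = [
    "ParseError",
    "parse_expr",
    "parse_model_text",
    "write_model_text",
]


class ParseError(ValueError):
    """Syntax or consistency error in a rule file (carries line/column)."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f"line {line}"
            if column is not None:
                loc += f", column {column}"
            loc = f" ({loc})"
        super().__init__(message + loc)
        self.line = line
        self.column = column


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<const>[01])(?![A-Za-z0-9_/])|(?P<ident>[A-Za-z][A-Za-z0-9_/]*))"
)
_KEYWORDS = ("and", "or", "not")


def _tokenize_expr(text: str, line: int | None):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].lstrip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r}", line, pos + 1)
        if m.group("lpar"):
            tokens.append(("(", m.start("lpar")))
        elif m.group("rpar"):
            tokens.append((")", m.start("rpar")))
        elif m.group("const") is not None:
            tokens.append((("const", m.group("const") == "1"), m.start("const")))
        else:
            word = m.group("ident")
            if word in _KEYWORDS:
                tokens.append((word, m.start("ident")))
            else:
                tokens.append((("var", word), m.start("ident")))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive descent over: or_expr -> and_expr (``or`` and_expr)* ..."""

    def __init__(self, tokens, line):
        self.tokens = tokens
        self.line = line
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pop(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, msg):
        col = self.tokens[self.i][1] + 1 if self.i < len(self.tokens) else None
        raise ParseError(msg, self.line, col)

    def parse(self) -> BoolExpr:
        expr = self.or_expr()
        if self.i != len(self.tokens):
            self.fail("trailing tokens after expression")
        return expr

    def or_expr(self) -> BoolExpr:
        parts = [self.and_expr()]
        while self.peek() == "or":
            self.pop()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def and_expr(self) -> BoolExpr:
        parts = [self.not_expr()]
        while self.peek() == "and":
            self.pop()
            parts.append(self.not_expr())
        return parts[0] if len(parts) == 1 else And(*parts)

    def not_expr(self) -> BoolExpr:
        if self.peek() == "not":
            self.pop()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> BoolExpr:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.line)
        if tok == "(":
            self.pop()
            expr = self.or_expr()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.pop()
            return expr
        if isinstance(tok, tuple):
            kind, value = self.pop()[0]
            return Const(value) if kind == "const" else Var(value)
        self.fail(f"unexpected token {tok!r}")


def parse_expr(text: str, line: int | None = None) -> BoolExpr:
    """Parse one Boolean expression."""
    tokens = _tokenize_expr(text, line)
    if not tokens:
        raise ParseError("empty expression", line)
    return _ExprParser(tokens, line).parse()


_NODE_RE = re.compile(
    r"node\s+(?P<name>\S+)"
    r"(?:\s+levels=(?P<levels>\d+))?"
    r"(?:\s+class=(?P<cls>\w+))?"
    r"(?:\s+pathway=(?P<pathway>\S+))?"
    r"(?P<source>\s+source)?\s*$"
)
_RULE_RE = re.compile(r"rule\s+(?P<name>\S+)\s*=\s*(?P<expr>.+)$")
_OUTCOME_RE = re.compile(r"outcome\s+(?P<name>\S+)\s+weights=(?P<weights>[\d.,eE+-]+)\s*$")


def parse_model_text(text: str) -> LogicalModel:
    """Parse a rule file into a validated :class:`LogicalModel`.

    Raises :class:`ParseError` on syntax errors, undeclared literals,
    duplicate rules or missing rules.  Optional ``outcome`` lines are
    collected on ``model.outcome_weights`` (node -> list of weights).
    """
    model = LogicalModel()
    outcome_weights: dict[str, list[float]] = {}
    rule_lines: list[tuple[int, str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("node"):
            m = _NODE_RE.fullmatch(line)
            if m is None:
                raise ParseError("malformed node declaration", lineno)
            name = m.group("name")
            if not IDENT_RE.fullmatch(name):
                raise ParseError(f"invalid node name {name!r}", lineno)
            if any(spec.name == name for spec in model.nodes):
                raise ParseError(f"duplicate node {name}", lineno)
            model.nodes.append(
                NodeSpec(
                    name=name,
                    n_levels=int(m.group("levels") or 2),
                    update_class=m.group("cls") or "fast",
                    pathway=m.group("pathway") or "",
                    is_source=bool(m.group("source")),
                )
            )
        elif line.startswith("rule"):
            m = _RULE_RE.fullmatch(line)
            if m is None:
                raise ParseError("malformed rule", lineno)
            rule_lines.append((lineno, m.group("name"), m.group("expr")))
        elif line.startswith("outcome"):
            m = _OUTCOME_RE.fullmatch(line)
            if m is None:
                raise ParseError("malformed outcome line", lineno)
            try:
                weights = [float(w) for w in m.group("weights").split(",")]
            except ValueError:
                raise ParseError("malformed outcome weights", lineno) from None
            outcome_weights[m.group("name")] = weights
        else:
            raise ParseError(f"unrecognized statement {line.split()[0]!r}", lineno)

    declared = set(model.indicators)
    for lineno, name, expr_text in rule_lines:
        if name not in declared:
            raise ParseError(f"rule for undeclared indicator {name}", lineno)
        if name in model.rules:
            raise ParseError(f"duplicate rule for {name}", lineno)
        expr = parse_expr(expr_text, lineno)
        bad = sorted(expr.literals() - declared)
        if bad:
            raise ParseError(f"undeclared literal {bad[0]}", lineno)
        model.rules[name] = expr

    for spec in model.nodes:
        for ind in spec.indicators:
            if ind not in model.rules:
                raise ParseError(f"missing rule for {ind}")

    for name, weights in outcome_weights.items():
        spec = model.node(name)
        if len(weights) != spec.n_levels:
            raise ParseError(f"outcome {name}: expected {spec.n_levels} weights")
    model.outcome_weights = outcome_weights

    diags = validate_model(model)
    if diags:
        raise ParseError("; ".join(diags))
    return model


def write_model_text(model: LogicalModel, header: str | None = None) -> str:
    """Serialize a model to the rule-file dialect (inverse of the parser)."""
    lines = []
    if header:
        lines.extend(f"# {ln}" for ln in header.splitlines())
        lines.append("")
    for spec in model.nodes:
        parts = [f"node {spec.name}", f"levels={spec.n_levels}", f"class={spec.update_class}"]
        if spec.pathway:
            parts.append(f"pathway={spec.pathway}")
        if spec.is_source:
            parts.append("source")
        lines.append(" ".join(parts))
    lines.append("")
    for spec in model.nodes:
        for ind in spec.indicators:
            lines.append(f"rule {ind} = {model.rules[ind].to_text()}")
    weights = getattr(model, "outcome_weights", None)
    if weights:
        lines.append("")
        for name, ws in weights.items():
            lines.append(f"outcome {name} weights={','.join(repr(float(w)) for w in ws)}")
    return "\n".join(lines) + "\n"
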