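"""Random logical-model generator for property-based testing.

Generates models with the structural features the analysis assumes —
mixed Boolean/multi-level nodes, self-sustaining source nodes, fast/slow
kinetic classes — so that every engine, attractor, outcome and screen
operation is testable without any hand-curated fixture.  Rules are drawn
as random truth tables (guaranteeing coverage of non-monotone logic,
e.g. dominant inhibitors) and converted to disjunctive-normal-form
expressions, so generated models serialize to the standard rule dialect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .logic import And, Const, LogicalModel, NodeSpec, Not, Or, Var
from .outcomes import OutcomeWeights

__all__ = ["GeneratorConfig", "random_model", "expression_from_truth_table", "random_outcome_annotation"]

_PATHWAYS = ("RTK", "PI3K", "MAPK", "AKT", "mTORC1", "ER", "Apoptosis", "Proliferation")


@dataclass
class GeneratorConfig:
    n_nodes: int = 10
    multilevel_fraction: float = 0.3
    max_levels: int = 4
    max_in_degree: int = 3
    rule_bias: float = 0.5  # probability that a random truth-table entry is ON
    fast_fraction: float = 0.6
    source_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multilevel_fraction", "rule_bias", "fast_fraction", "source_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1")
        if self.max_levels < 2:
            raise ValueError("max_levels must be >= 2")


def expression_from_truth_table(names, outputs):
    """DNF expression over ``names`` matching the given truth table.

    ``outputs`` is ordered as in :func:`bcnet.logic.truth_table`:
    inputs counted in binary with the *last* name as least-significant...
    actually with ``itertools.product`` order (first name most significant).
    """
    if not any(outputs):
        return Const(False)
    if all(outputs):
        return Const(True)
    terms = []
    for bits, out in zip(itertools.product((False, True), repeat=len(names)), outputs):
        if not out:
            continue
        lits = [Var(n) if b else Not(Var(n)) for n, b in zip(names, bits)]
        terms.append(lits[0] if len(lits) == 1 else And(*lits))
    return terms[0] if len(terms) == 1 else Or(*terms)


def random_model(cfg: GeneratorConfig) -> LogicalModel:
    """A valid random :class:`LogicalModel`, reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    n_sources = max(1, int(round(cfg.source_fraction * n))) if cfg.source_fraction > 0 else 0

    model = LogicalModel()
    for i in range(n):
        is_source = i < n_sources
        multi = cfg.max_levels >= 3 and rng.random() < cfg.multilevel_fraction
        levels = int(rng.integers(3, cfg.max_levels + 1)) if multi else 2
        model.nodes.append(
            NodeSpec(
                name=f"N{i + 1}",
                n_levels=levels,
                update_class="fast" if rng.random() < cfg.fast_fraction else "slow",
                pathway=str(rng.choice(_PATHWAYS)),
                is_source=is_source,
            )
        )

    all_indicators = model.indicators
    for spec in model.nodes:
        for ind in spec.indicators:
            if spec.is_source:
                model.rules[ind] = Var(ind)
                continue
            d = int(rng.integers(1, cfg.max_in_degree + 1))
            d = min(d, len(all_indicators))
            regs = sorted(rng.choice(len(all_indicators), size=d, replace=False))
            names = [all_indicators[j] for j in regs]
            outputs = tuple(bool(rng.random() < cfg.rule_bias) for _ in range(2**d))
            model.rules[ind] = expression_from_truth_table(names, outputs)
    return model


def random_outcome_annotation(model: LogicalModel, seed: int = 0):
    """Designate two multi-level nodes as outcomes with monotone weights.

    Returns (model, OutcomeWeights, (first outcome node, second)).  The
    weights start at 0, end at 1 and are non-decreasing.  Raises if the
    model has fewer than two multi-level nodes.
    """
    rng = np.random.default_rng(seed)
    multi = [spec for spec in model.nodes if spec.n_levels >= 3]
    if len(multi) < 2:
        raise ValueError("model needs at least two multi-level nodes for outcome annotation")
    picks = rng.choice(len(multi), size=2, replace=False)
    chosen = (multi[int(picks[0])], multi[int(picks[1])])
    weights = {}
    for spec in chosen:
        inner = np.sort(rng.random(spec.n_levels - 2))
        weights[spec.name] = [0.0, *[float(w) for w in inner], 1.0]
    model.outcome_weights = weights
    model.outcome_nodes = tuple(spec.name for spec in chosen)
    return model, OutcomeWeights(weights), model.outcome_nodes
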