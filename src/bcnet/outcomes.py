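"""Normalized apoptosis/proliferation scores from outcome-node occupancies.

The two multi-level outcome nodes (Apoptosis, Proliferation) are
summarized as a weighted, [0, 1]-normalized score: each level carries a
weight (0 at level 0, 1 at the top level), and the score of an ensemble
is the occupancy-weighted average.  Default weights ship with the model
fixtures; they are calibrated so that the printed anchor values of the
reference scenarios are reproduced (see the fixture file headers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import EnsembleTimecourse

__all__ = ["OutcomeWeights", "outcome_norm", "summarize_endpoint", "score_timecourse"]

#: endpoint convergence check: scores must move less than this over the
#: trailing window for the endpoint to count as stabilized
CONVERGENCE_TOL = 0.01
CONVERGENCE_WINDOW = 10.0


@dataclass
class OutcomeWeights:
    """Level -> weight maps for the outcome nodes.

    Weights must be non-decreasing in level, start at 0 and end at 1
    (by default) so scores are normalized to [0, 1].
    """

    weights: dict = field(default_factory=dict)  # node -> list of weights per level

    def __post_init__(self) -> None:
        for node, ws in self.weights.items():
            ws = [float(w) for w in ws]
            if any(b < a for a, b in zip(ws, ws[1:])):
                raise ValueError(f"{node}: weights must be non-decreasing")
            if not all(0.0 <= w <= 1.0 for w in ws):
                raise ValueError(f"{node}: weights must lie in [0, 1]")
            self.weights[node] = ws

    def for_node(self, node: str) -> list:
        return self.weights[node]

    @classmethod
    def from_model(cls, model) -> "OutcomeWeights":
        """Weights attached to a parsed model's ``outcome`` lines."""
        ws = getattr(model, "outcome_weights", None)
        if not ws:
            raise ValueError("model carries no outcome weights")
        return cls(dict(ws))


def outcome_norm(occupancy, weights) -> float:
    """Weighted, normalized score of one level-occupancy distribution.

    ``occupancy`` maps level -> fraction (fractions sum to 1);
    ``weights`` is the level->weight list for that node.
    """
    total = sum(occupancy.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"occupancy fractions sum to {total}, not 1")
    score = 0.0
    for level, frac in occupancy.items():
        if level >= len(weights):
            raise KeyError(f"level {level} missing from weights")
        score += frac * weights[level]
    return float(score)


def score_timecourse(tc: EnsembleTimecourse, node: str, weights: OutcomeWeights) -> np.ndarray:
    """Score at every grid point (full timecourse of the normalized score)."""
    occ = tc.occupancy_of(node)
    w = np.asarray(weights.for_node(node))
    return occ @ w


def summarize_endpoint(tc: EnsembleTimecourse, weights: OutcomeWeights, apoptosis="Apoptosis", proliferation="Proliferation"):
    """(Apoptosis_norm, Proliferation_norm) at the final grid point.

    Warns if the scores are still moving (more than ``CONVERGENCE_TOL``
    over the trailing ``CONVERGENCE_WINDOW`` scaled units), or if a clamp
    onset lies beyond the horizon.
    """
    scores = []
    for node in (apoptosis, proliferation):
        series = score_timecourse(tc, node, weights)
        tail = tc.grid >= tc.grid[-1] - CONVERGENCE_WINDOW
        if tail.sum() > 1 and (series[tail].max() - series[tail].min()) > CONVERGENCE_TOL:
            warnings.warn(
                f"{node} score moved {series[tail].max() - series[tail].min():.3f} over the "
                f"last {CONVERGENCE_WINDOW} scaled units; endpoint may not be stabilized"
            )
        scores.append(float(series[-1]))
    return tuple(scores)
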