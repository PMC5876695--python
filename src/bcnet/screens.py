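"""Exhaustive single/double perturbation screens over a baseline drug protocol.

Every possible sustained constitutive activation or inactivation of the
network nodes — set-level clamps to each level, plus cap clamps below
each level >= 2 for multi-level nodes — is combined with the baseline
protocol (typically PI3K inhibition from t = 2), scored by the endpoint
apoptosis/proliferation propensities, grouped by behavioral equivalence
(identical endpoint activity vectors within tolerance) and ranked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Clamp, Protocol, run_ensemble
from .logic import LogicalModel
from .outcomes import OutcomeWeights, summarize_endpoint

__all__ = [
    "Perturbation",
    "ScreenRow",
    "enumerate_perturbations",
    "run_screen",
    "group_and_rank",
    "filter_resistance",
    "filter_synergy",
]


@dataclass(frozen=True)
class Perturbation:
    """Sustained intervention(s) applied from t = 0 with no offset.

    ``targets`` is a tuple of (node, kind, level) with kind in
    {"set_level", "cap_level"}; the empty tuple is the screen control.
    """

    targets: tuple = ()

    def __post_init__(self) -> None:
        nodes = [t[0] for t in self.targets]
        if len(set(nodes)) != len(nodes):
            raise ValueError("perturbation targets must be distinct nodes")

    @property
    def arity(self) -> int:
        return len(self.targets)

    def label(self) -> str:
        if not self.targets:
            return "control"
        parts = []
        for node, kind, level in self.targets:
            parts.append(f"{node} = {level}" if kind == "set_level" else f"{node} < {level}")
        return "; ".join(parts)

    def clamps(self) -> list:
        return [Clamp(kind=kind, node=node, level=level, onset=0.0) for node, kind, level in self.targets]

    def mechanisms(self, model: LogicalModel) -> tuple:
        return tuple(model.node(node).pathway for node, _, _ in self.targets)


def enumerate_perturbations(
    model: LogicalModel,
    arity_max: int = 1,
    include_caps: bool = True,
    excluded_nodes=(),
) -> list:
    """All single (and optionally double) sustained clamps.

    Per node with L levels: set-level clamps to every level 0..L-1 and,
    when ``include_caps``, cap clamps below each level >= 2 (L-2 caps).
    Pairs are unordered with distinct target nodes.
    """
    excluded = set(excluded_nodes)
    singles = []
    for spec in model.nodes:
        if spec.name in excluded:
            continue
        for level in range(spec.n_levels):
            singles.append((spec.name, "set_level", level))
        if include_caps:
            for bound in range(2, spec.n_levels):
                singles.append((spec.name, "cap_level", bound))

    out = [Perturbation((t,)) for t in singles]
    if arity_max >= 2:
        for a, b in itertools.combinations(singles, 2):
            if a[0] != b[0]:
                out.append(Perturbation((a, b)))
    return out


@dataclass
class ScreenRow:
    """One scored screen entry."""

    perturbation: Perturbation
    apoptosis: float
    proliferation: float
    mechanisms: tuple
    activity_vector: np.ndarray = field(repr=False, default=None)
    target_mask: np.ndarray = field(repr=False, default=None)  # True on the
    # indicator columns of this row's own clamped nodes (ignored when
    # testing network-equivalence, since a clamp trivially differs there)
    se: float = 0.0
    n: int = 0
    group_id: int | None = None

    def label(self) -> str:
        return self.perturbation.label()


def _target_mask(row: ScreenRow) -> np.ndarray:
    if row.target_mask is None:
        return np.zeros(row.activity_vector.shape, dtype=bool)
    return row.target_mask


def _endpoint_se(tc, node, weights):
    """Monte-Carlo standard error of one endpoint score (exact sample SE)."""
    occ = tc.occupancy_of(node)[-1]
    w = np.asarray(weights.for_node(node))
    mean = float(occ @ w)
    var = float(occ @ (w**2)) - mean**2
    return float(np.sqrt(max(var, 0.0) / tc.replicates))


def run_screen(
    model: LogicalModel,
    baseline: Protocol,
    perturbations,
    weights: OutcomeWeights,
    replicates: int | None = None,
    include_control: bool = True,
    outcome_nodes: tuple = ("Apoptosis", "Proliferation"),
) -> list:
    """Score each perturbation on top of the baseline protocol.

    Perturbation clamps start at t = 0, before the baseline drug clamps.
    Each perturbation runs with a deterministic child seed of the baseline
    seed, so the whole screen is reproducible.
    """
    todo = list(perturbations)
    if include_control and not any(p.arity == 0 for p in todo):
        todo.insert(0, Perturbation())

    rows = []
    for i, pert in enumerate(todo):
        child = int(np.random.SeedSequence([baseline.seed, i]).generate_state(1)[0] % (2**31))
        protocol = baseline.with_clamps(pert.clamps(), seed=child)
        if replicates is not None:
            protocol.replicates = replicates
        tc = run_ensemble(model, protocol)
        apop_node, prolif_node = outcome_nodes
        apop, prolif = summarize_endpoint(
            tc, weights, apoptosis=apop_node, proliferation=prolif_node
        )
        se = max(_endpoint_se(tc, apop_node, weights), _endpoint_se(tc, prolif_node, weights))
        target_nodes = {node for node, _, _ in pert.targets}
        mask = np.array(
            [model.indicator_node(v).name in target_nodes for v in tc.variables], dtype=bool
        )
        rows.append(
            ScreenRow(
                perturbation=pert,
                apoptosis=apop,
                proliferation=prolif,
                mechanisms=pert.mechanisms(model),
                activity_vector=tc.activities[-1].copy(),
                target_mask=mask,
                se=se,
                n=tc.replicates,
            )
        )
    return rows


def group_and_rank(
    rows,
    metric: str = "Apoptosis",
    ascending: bool = True,
    tolerance: float | None = None,
    n_se: float = 3.0,
) -> pd.DataFrame:
    """Merge behaviorally equivalent rows and rank groups by the metric.

    Rows whose final activity vectors agree — outside the indicator
    columns of their own clamped nodes — are merged into one group
    listing all member perturbations; groups are sorted by the metric,
    ties broken lexicographically by perturbation label.  With
    ``tolerance`` given, agreement means max absolute difference within
    it (0 groups only identical rows); otherwise each element is
    compared within ``n_se`` pooled binomial Monte-Carlo standard errors
    (plus a small absolute floor).
    """
    key = "apoptosis" if metric.lower().startswith("apop") else "proliferation"

    def matches(a: ScreenRow, b: ScreenRow) -> bool:
        if a.activity_vector is None or b.activity_vector is None:
            return False
        # the endpoint scores are the effect summary and must agree even
        # when a clamped outcome node is excluded from the vector check
        score_tol = tolerance if tolerance is not None else n_se * max(a.se, b.se, 0.002)
        if abs(a.apoptosis - b.apoptosis) > score_tol:
            return False
        if abs(a.proliferation - b.proliferation) > score_tol:
            return False
        mask = ~(_target_mask(a) | _target_mask(b))
        if not mask.any():
            return False
        va, vb = a.activity_vector[mask], b.activity_vector[mask]
        if tolerance is not None:
            return float(np.max(np.abs(va - vb))) <= tolerance
        na, nb = max(a.n, 1), max(b.n, 1)
        tol = n_se * np.sqrt(va * (1 - va) / na + vb * (1 - vb) / nb) + 0.005
        return bool(np.all(np.abs(va - vb) <= tol))

    groups: list = []  # lists of rows; the first member is the representative
    for row in sorted(rows, key=ScreenRow.label):
        for members in groups:
            if matches(row, members[0]):
                members.append(row)
                break
        else:
            groups.append([row])
    groups = [(None, members) for members in groups]

    records = []
    for gid, (_, members) in enumerate(groups):
        for row in members:
            row.group_id = gid
        scores = [getattr(r, key) for r in members]
        records.append(
            {
                "perturbations": "; ".join(sorted(r.label() for r in members)),
                "Apoptosis_norm": float(np.mean([r.apoptosis for r in members])),
                "Proliferation_norm": float(np.mean([r.proliferation for r in members])),
                "mechanism": "; ".join(sorted({m for r in members for m in r.mechanisms}) or [""]),
                "group": gid,
                "n_members": len(members),
            }
        )
    table = pd.DataFrame.from_records(records)
    table = table.sort_values(
        [ "Apoptosis_norm" if key == "apoptosis" else "Proliferation_norm", "perturbations"],
        ascending=[ascending, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def _control_row(rows):
    for row in rows:
        if row.perturbation.arity == 0:
            return row
    raise ValueError("no control row in screen results")


def filter_resistance(rows, control: ScreenRow | None = None, n_se: float = 3.0) -> list:
    """Rows that blunt the drug effect: lower apoptosis and/or higher
    proliferation than the control, by more than ``n_se`` pooled
    Monte-Carlo standard errors.  The control itself is excluded."""
    control = _control_row(rows) if control is None else control
    out = []
    for row in rows:
        if row is control or row.perturbation.arity == 0:
            continue
        eps = n_se * max(row.se, control.se)
        if row.apoptosis < control.apoptosis - eps or row.proliferation > control.proliferation + eps:
            out.append(row)
    return out


def filter_synergy(rows, control: ScreenRow | None = None, n_se: float = 3.0) -> list:
    """Rows that potentiate the drug: higher apoptosis and/or lower
    proliferation than the control.  The control itself is excluded."""
    control = _control_row(rows) if control is None else control
    out = []
    for row in rows:
        if row is control or row.perturbation.arity == 0:
            continue
        eps = n_se * max(row.se, control.se)
        if row.apoptosis > control.apoptosis + eps or row.proliferation < control.proliferation - eps:
            out.append(row)
    return out
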