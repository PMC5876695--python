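"""Perturbation enumeration, screening, grouping and filtering."""

import math

import numpy as np
import pytest

from bcnet.engine import Protocol
from bcnet.ruleformat import parse_model_text
from bcnet.screens import (
    Perturbation,
    ScreenRow,
    enumerate_perturbations,
    filter_resistance,
    filter_synergy,
    group_and_rank,
    run_screen,
)
from bcnet.synth import GeneratorConfig, random_model, random_outcome_annotation

THREE_LEVEL = """
node S levels=2 class=fast source
node X levels=3 class=fast
rule S = S
rule X = S
rule X_2 = S and X
"""


class TestEnumeration:
    def test_toy_singles_two_per_boolean_node(self, toy):
        perts = enumerate_perturbations(toy, arity_max=1)
        assert len(perts) == 18  # 9 Boolean nodes x {set 0, set 1}

    def test_three_level_node_contributes_four_singles(self):
        model = parse_model_text(THREE_LEVEL)
        perts = enumerate_perturbations(model, arity_max=1, excluded_nodes=["S"])
        labels = {p.label() for p in perts}
        assert labels == {"X = 0", "X = 1", "X = 2", "X < 2"}

    def test_pair_count_formula(self):
        model = random_model(GeneratorConfig(n_nodes=6, multilevel_fraction=0.5, seed=2))
        singles = enumerate_perturbations(model, arity_max=1)
        both = enumerate_perturbations(model, arity_max=2)
        per_node = {}
        for p in singles:
            per_node.setdefault(p.targets[0][0], 0)
            per_node[p.targets[0][0]] += 1
        same_node_pairs = sum(math.comb(k, 2) for k in per_node.values())
        expected_pairs = math.comb(len(singles), 2) - same_node_pairs
        assert len(both) - len(singles) == expected_pairs

    def test_excluded_nodes_respected(self, bc_model):
        # the presentation filter for double screens drops outcome pathways
        excluded = [
            spec.name for spec in bc_model.nodes if spec.pathway in ("Apoptosis", "Proliferation")
        ]
        perts = enumerate_perturbations(bc_model, arity_max=1, excluded_nodes=excluded)
        touched = {node for p in perts for node, _, _ in p.targets}
        assert touched.isdisjoint(excluded)
        assert "BIM" in excluded and "pRb" in excluded

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Perturbation((("X", "set_level", 0), ("X", "set_level", 1)))


def _rows(values):
    rows = []
    for label, apop, prolif, vec in values:
        pert = Perturbation() if label == "control" else Perturbation(((label, "set_level", 1),))
        rows.append(
            ScreenRow(
                perturbation=pert,
                apoptosis=apop,
                proliferation=prolif,
                mechanisms=("",),
                activity_vector=np.asarray(vec, dtype=float),
                target_mask=np.zeros(len(vec), dtype=bool),
                se=0.01,
                n=1000,
            )
        )
    return rows


class TestGroupingAndFilters:
    def test_identical_rows_group_at_zero_tolerance(self):
        rows = _rows(
            [("A", 0.1, 0.5, [1, 0, 1]), ("B", 0.1, 0.5, [1, 0, 1]), ("C", 0.3, 0.2, [0, 0, 1])]
        )
        table = group_and_rank(rows, tolerance=0.0)
        assert len(table) == 2
        assert "A = 1; B = 1" in table["perturbations"].tolist()

    def test_ranking_orders_by_metric_with_ties_lexicographic(self):
        rows = _rows(
            [("B", 0.2, 0.1, [0, 1, 0]), ("A", 0.2, 0.3, [1, 1, 0]), ("C", 0.1, 0.2, [1, 0, 0])]
        )
        table = group_and_rank(rows, metric="Apoptosis", ascending=True, tolerance=0.0)
        assert table["perturbations"].tolist() == ["C = 1", "A = 1", "B = 1"]

    def test_filters_split_by_direction_and_exclude_control(self):
        rows = _rows(
            [
                ("control", 0.70, 0.25, [0, 0, 0]),
                ("res", 0.20, 0.25, [1, 0, 0]),
                ("syn", 0.90, 0.10, [0, 1, 0]),
                ("null", 0.70, 0.25, [0, 0, 1]),
            ]
        )
        res = filter_resistance(rows)
        syn = filter_synergy(rows)
        assert [r.label() for r in res] == ["res = 1"]
        assert [r.label() for r in syn] == ["syn = 1"]


class TestRunScreen:
    @pytest.fixture(scope="class")
    def annotated(self):
        model = random_model(
            GeneratorConfig(n_nodes=7, multilevel_fraction=0.6, max_levels=3, seed=8)
        )
        model, weights, (apop, prolif) = random_outcome_annotation(model, seed=8)
        return model, weights, apop, prolif

    def test_screen_smoke_on_random_model(self, annotated):
        model, weights, apop, prolif = annotated
        init = {v: False for v in model.indicators}
        baseline = Protocol(initial_states=[(init, 1.0)], horizon=30.0, replicates=100, seed=5)
        perts = enumerate_perturbations(model, arity_max=1)[:6]
        rows = run_screen(
            model, baseline, perts, weights, replicates=100, outcome_nodes=(apop, prolif)
        )
        assert len(rows) == 7  # control + 6
        for row in rows:
            assert 0.0 <= row.apoptosis <= 1.0
            assert 0.0 <= row.proliferation <= 1.0

    def test_screen_deterministic_per_seed(self, annotated):
        model, weights, apop, prolif = annotated
        init = {v: False for v in model.indicators}
        baseline = Protocol(initial_states=[(init, 1.0)], horizon=20.0, replicates=100, seed=6)
        perts = enumerate_perturbations(model, arity_max=1)[:3]
        a = run_screen(model, baseline, perts, weights, replicates=100, outcome_nodes=(apop, prolif))
        b = run_screen(model, baseline, perts, weights, replicates=100, outcome_nodes=(apop, prolif))
        assert [(r.apoptosis, r.proliferation) for r in a] == [
            (r.apoptosis, r.proliferation) for r in b
        ]
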