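"""Shipped fixtures: toy network exactness and the ER+ reconstruction.

The breast cancer fixture is a synthetic reconstruction built from
published mechanistic descriptions (see the fixture header); these tests
check the behaviors the reconstruction was designed to exhibit.
"""

import itertools

import numpy as np
import pytest

from bcnet import models
from bcnet.engine import Clamp, Protocol, run_ensemble
from bcnet.logic import validate_model
from bcnet.outcomes import score_timecourse, summarize_endpoint
from bcnet.ruleformat import parse_expr


class TestToyModel:
    def test_printed_rule_examples(self, toy):
        base = {v: False for v in toy.indicators}
        # PI3K activates in the presence of either active RTK or active RAS
        assert toy.rules["PI3K"].evaluate({**base, "RTK": True, "RAS": False})
        assert toy.rules["PI3K"].evaluate({**base, "RTK": False, "RAS": True})
        # the transcriptional response needs both AKT and MEK/ERK
        assert not toy.rules["TF"].evaluate({**base, "AKT": True})
        assert toy.rules["TF"].evaluate({**base, "AKT": True, "MEK/ERK": True})
        # PIP3 is produced by PI3K
        assert toy.rules["PIP3"].evaluate({**base, "PI3K": True})

    def test_growth_factor_self_sustains(self, toy):
        assert toy.rules["GF"].evaluate({"GF": True})
        assert not toy.rules["GF"].evaluate({"GF": False})


class TestBreastCancerFixture:
    def test_validates_cleanly(self, bc_model):
        assert validate_model(bc_model) == []

    def test_node_census(self, bc_model):
        biological = [s for s in bc_model.nodes if s.pathway != "drug"]
        drugs = [s for s in bc_model.nodes if s.pathway == "drug"]
        assert len(drugs) == 7
        assert {d.name for d in drugs} == set(models.DRUGS)
        sources = [s for s in biological if s.is_source]
        assert len(sources) == 13
        multistate = [s for s in biological if s.n_levels > 2]
        assert len(multistate) == 14
        assert bc_model.node("Apoptosis").n_levels == 4
        assert bc_model.node("Proliferation").n_levels == 5

    def test_akt_rule_matches_printed_truth_table(self, bc_model):
        printed = parse_expr(
            "(PIP3 or PIP3_2) and (PDK1_pm or mTORC2_pm) and (not Ipatasertib or PIP3_2)"
        )
        names = sorted(printed.literals())
        assert len(names) == 5
        for bits in itertools.product((False, True), repeat=5):
            state = dict(zip(names, bits))
            assert bc_model.rules["AKT"].evaluate(state) == printed.evaluate(state)

    def test_akt_ipatasertib_escape_at_high_pip3(self, bc_model):
        state = {
            "PIP3": True,
            "PIP3_2": True,
            "PDK1_pm": False,
            "mTORC2_pm": True,
            "Ipatasertib": True,
        }
        assert bc_model.rules["AKT"].evaluate(state)

    def test_er_transcription_2_requires_kmt2d(self, bc_model):
        state = {"KMT2D": False, "FOXA1": True, "PBX1": True, "ESR1_2": True, "ER": True}
        assert not bc_model.rules["ER_transcription_2"].evaluate(state)
        state["KMT2D"] = True
        assert bc_model.rules["ER_transcription_2"].evaluate(state)


class TestCancerousState:
    def test_six_steady_states_with_bcl2_bim_pattern(self, er_model):
        ensemble = models.cancerous_ensemble(er_model)
        assert len(ensemble) == 6
        decoded = [er_model.decode(state) for state, _ in ensemble]
        for levels in decoded:
            assert levels["Apoptosis"] == 0
            assert levels["Proliferation"] in (3, 4)
            assert levels["E2F"] in (2, 3)
            # BIM may be on only when BCL2 counteracts it
            assert not (levels["BIM"] == 1 and levels["BCL2"] == 0)
        combos = {(lv["BCL2"], lv["BIM"]) for lv in decoded}
        assert combos == {(0, 0), (1, 1), (1, 0)}

    def test_ensemble_is_exactly_the_apoptosis_free_fixed_points(self, er_model):
        from bcnet.attractors import find_fixed_points

        fps = find_fixed_points(er_model)
        apop0 = [a for a in fps if a.levels["Apoptosis"] == 0]
        ensemble = models.cancerous_ensemble(er_model)
        assert {tuple(sorted(s.items())) for s, _ in ensemble} == {
            tuple(sorted(a.states[0].items())) for a in apop0
        }


class TestPI3KInhibition:
    def test_endpoint_scores(self, pi3ki_timecourse, weights):
        apop, prolif = summarize_endpoint(pi3ki_timecourse, weights)
        assert apop == pytest.approx(0.70, abs=0.05)
        assert prolif == pytest.approx(0.25, abs=0.03)

    def test_initial_scores(self, pi3ki_timecourse, weights):
        apop0 = score_timecourse(pi3ki_timecourse, "Apoptosis", weights)[0]
        assert apop0 == pytest.approx(0.0, abs=1e-9)

    def test_proliferation_dips_before_rebound(self, pi3ki_timecourse, weights):
        series = score_timecourse(pi3ki_timecourse, "Proliferation", weights)
        post_drug = series[3:]
        assert post_drug.min() < series[-1] - 0.02

    def test_fast_nodes_fall_before_slow_nodes_rise(self, pi3ki_timecourse):
        tc = pi3ki_timecourse
        akt_off = tc.grid[np.flatnonzero(tc.activity("AKT") < 0.5)[0]]
        mtorc1_off = tc.grid[np.flatnonzero(tc.activity("mTORC1") < 0.5)[0]]
        esr1_up = tc.grid[np.flatnonzero(tc.activity("ESR1_2") > 0.9)[0]]
        bim_up = tc.grid[np.flatnonzero(tc.activity("BIM") > 0.9)[0]]
        assert max(akt_off, mtorc1_off) < min(esr1_up, bim_up)


class TestResistanceScenarios:
    @pytest.fixture(scope="class")
    def endpoints(self, er_model, weights):
        out = {}
        scenarios = models.named_protocols(er_model, replicates=500, seed=13)
        for name in ("pi3ki", "pi3ki_pim", "pi3ki_sgk1_pdk1", "pi3ki_pim90"):
            tc = run_ensemble(er_model, scenarios[name].protocol)
            out[name] = {
                "scores": summarize_endpoint(tc, weights),
                "mtorc1": float(tc.activity("mTORC1")[-1]),
            }
        return out

    def test_pim_blocks_apoptosis_and_keeps_proliferation(self, endpoints):
        apop, prolif = endpoints["pi3ki_pim"]["scores"]
        assert apop == pytest.approx(0.0, abs=0.02)
        assert prolif > endpoints["pi3ki"]["scores"][1] + 0.1

    def test_sgk1_partial_resistance(self, endpoints):
        apop, prolif = endpoints["pi3ki_sgk1_pdk1"]["scores"]
        assert apop == pytest.approx(0.25, abs=0.05)
        assert prolif == pytest.approx(0.25, abs=0.05)

    def test_pim90_sits_between_pim_and_sgk1(self, endpoints):
        full = endpoints["pi3ki_pim"]
        partial = endpoints["pi3ki_pim90"]
        # 90%-effective PIM: lower mTORC1 activity and proliferation,
        # higher apoptosis than fully effective PIM
        assert partial["mtorc1"] < full["mtorc1"] - 0.02
        assert partial["scores"][0] > full["scores"][0] + 0.02
        assert partial["scores"][1] < full["scores"][1] - 0.05


class TestValidationSuite:
    def test_all_checks_pass(self):
        results = models.table4_validation_suite(replicates=300, seed=7)
        assert len(results) >= 5
        assert all(ok for _, ok in results), [name for name, ok in results if not ok]


class TestNamedProtocols:
    def test_registry_contents(self, er_model):
        scenarios = models.named_protocols(er_model, replicates=10, seed=0)
        assert {
            "pi3ki",
            "pi3ki_pim",
            "pi3ki_sgk1_pdk1",
            "pi3ki_pim90",
            "screen_baseline",
            "staggered_mtori_pi3ki",
        } <= set(scenarios)
        assert scenarios["screen_baseline"].protocol.horizon == 100.0
        assert scenarios["staggered_mtori_pi3ki"].protocol.horizon == 120.0

    def test_cancerous_count_guard(self, bc_model):
        # restoring PTEN kills PI3K signaling: no apoptosis-free steady state
        broken = models.er_plus_context_model({**models.ER_PLUS_CONTEXT, "PTEN": 1})
        with pytest.raises(ValueError, match="expected 6"):
            models.cancerous_ensemble(broken)
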