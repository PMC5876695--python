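"""General-asynchronous engine: time scaling, stepping, clamps, ensembles."""

import numpy as np
import pytest

from bcnet import models
from bcnet.attractors import _stg, exact_absorption
from bcnet.engine import (
    Clamp,
    Protocol,
    UpdateWeights,
    add_inhibitor,
    ga_step,
    micro_steps_for,
    run_ensemble,
    run_trajectory,
    scaled_time,
)
from bcnet.logic import And, Const, Not, Or, Var
from bcnet.synth import GeneratorConfig, random_model


class TestScaledTime:
    def test_equal_weights_unit(self, toy):
        # 9 equal-probability variables: 9 micro-steps = one time unit
        w = UpdateWeights.from_model(models.toy_rtk_model(tf_slow=False))
        with pytest.warns(UserWarning, match="no slow variables"):
            assert scaled_time(9, w) == pytest.approx(1.0)

    def test_slow_tf_unit(self, toy):
        # TF weight 1, eight signaling nodes weight 5: p_TF = 1/41
        w = UpdateWeights.from_model(toy)
        assert w.probability("TF") == pytest.approx(1 / 41)
        assert scaled_time(41, w) == pytest.approx(1.0)

    def test_mixed_class_unit(self):
        # 30 fast + 20 slow Boolean nodes: unit = 5*30 + 20 = 170 micro-steps
        weights = UpdateWeights(
            {f"f{i}": 5.0 for i in range(30)} | {f"s{i}": 1.0 for i in range(20)},
            unit_weight=1.0,
        )
        assert scaled_time(170, weights) == pytest.approx(1.0)

    def test_inverse_rounds_up(self, toy):
        w = UpdateWeights.from_model(toy)
        assert micro_steps_for(1.0, w) == 41
        assert micro_steps_for(1.01, w) == 42


class TestGaStep:
    def test_successor_set_matches_stg_oracle(self):
        model = random_model(GeneratorConfig(n_nodes=8, seed=12))
        names = model.indicators
        weights = UpdateWeights.from_model(model)
        rng = np.random.default_rng(0)
        state = {v: bool(rng.integers(2)) for v in names}

        # oracle: successors are {state with v -> f_v(state)} over all v
        _, free, _, S, F = _stg(model, [])
        code = sum(1 << j for j, v in enumerate(free) if state[v])
        expected = set()
        for j, v in enumerate(free):
            succ = dict(state)
            succ[v] = bool(F[code, j])
            expected.add(tuple(sorted(succ.items())))

        seen = set()
        for seed in range(400):
            nxt = ga_step(state, model, weights, rng=np.random.default_rng(seed))
            seen.add(tuple(sorted(nxt.items())))
        assert seen == expected

    def test_fixed_variable_leaves_state_unchanged(self, toy):
        state = toy.encode_levels({name: 0 for name in toy.node_names})
        weights = UpdateWeights.from_model(toy)
        nxt = ga_step(state, toy, weights, rng=np.random.default_rng(1))
        assert nxt == state  # all-OFF is a fixed point of the toy cascade

    def test_single_flip_property(self, toy):
        proto = Protocol(
            initial_states=[(toy.encode_levels({"GF": 1}), 1.0)],
            horizon=20.0,
            replicates=1,
            seed=3,
        )
        traj = run_trajectory(toy, proto)
        for a, b in zip(traj.states, traj.states[1:]):
            assert sum(a[v] != b[v] for v in a) <= 1


class TestTrajectories:
    def test_gf_on_reaches_all_on(self, toy):
        proto = Protocol(
            initial_states=[(toy.encode_levels({"GF": 1}), 1.0)], horizon=40.0, replicates=1, seed=0
        )
        final = run_trajectory(toy, proto).decoded_final()
        assert all(final[n] == 1 for n in toy.node_names)

    def test_rtki_clamp_reverts_to_initial(self, toy_drugs):
        proto = Protocol(
            initial_states=[(toy_drugs.encode_levels({"GF": 1}), 1.0)],
            clamps=[Clamp("set_level", "RTKi", 1, onset=20.0)],
            horizon=80.0,
            replicates=1,
            seed=0,
        )
        final = run_trajectory(toy_drugs, proto).decoded_final()
        assert final["GF"] == 1 and final["RTKi"] == 1
        assert all(final[n] == 0 for n in ("RTK", "RAS", "PI3K", "BRAF", "PIP3", "MEK/ERK", "AKT", "TF"))

    def test_ras_override_resists_rtki(self, toy_drugs):
        init = toy_drugs.encode_levels({"GF": 1, "RTKi": 1})
        proto = Protocol(
            initial_states=[(init, 1.0)],
            clamps=[
                Clamp("set_level", "RTKi", 1, onset=0.0),
                Clamp("rule_override", "RAS", onset=20.0, expr=Const(True)),
            ],
            horizon=100.0,
            replicates=1,
            seed=2,
        )
        final = run_trajectory(toy_drugs, proto).decoded_final()
        assert final["RTK"] == 0
        assert all(final[n] == 1 for n in ("RAS", "PI3K", "BRAF", "PIP3", "MEK/ERK", "AKT", "TF"))

    def test_meki_shuts_down_tf(self, toy_drugs):
        init = toy_drugs.encode_levels({"GF": 1, "RTKi": 1})
        proto = Protocol(
            initial_states=[(init, 1.0)],
            clamps=[
                Clamp("set_level", "RTKi", 1, onset=0.0),
                Clamp("rule_override", "RAS", onset=0.0, expr=Const(True)),
                Clamp("set_level", "MEKi", 1, onset=20.0),
            ],
            horizon=120.0,
            replicates=1,
            seed=2,
        )
        final = run_trajectory(toy_drugs, proto).decoded_final()
        assert final["TF"] == 0 and final["MEK/ERK"] == 0
        assert final["PI3K"] == 1  # PI3K branch stays active


class TestEnsembles:
    def test_activities_rise_and_tf_lags(self, toy):
        proto = Protocol(
            initial_states=[(toy.encode_levels({"GF": 1}), 1.0)],
            horizon=60.0,
            replicates=500,
            seed=5,
        )
        tc = run_ensemble(toy, proto)
        assert tc.activity("TF")[-1] > 0.99
        # transcription lags its regulators at every grid point
        lag = tc.activity("AKT") - tc.activity("TF")
        assert (lag >= -0.05).all() and lag.max() > 0.2

    def test_replicate_one_is_binary(self, toy):
        proto = Protocol(
            initial_states=[(toy.encode_levels({"GF": 1}), 1.0)], horizon=20.0, replicates=1, seed=6
        )
        tc = run_ensemble(toy, proto)
        assert set(np.unique(tc.activities)) <= {0.0, 1.0}

    def test_same_seed_reproduces(self, toy):
        proto = Protocol(
            initial_states=[(toy.encode_levels({"GF": 1}), 1.0)], horizon=30.0, replicates=200, seed=7
        )
        a = run_ensemble(toy, proto)
        b = run_ensemble(toy, proto)
        assert np.array_equal(a.activities, b.activities)
        assert np.array_equal(a.final_states, b.final_states)

    def test_occupancy_sums_to_one(self, er_model, cancerous):
        proto = Protocol(
            initial_states=cancerous,
            clamps=[Clamp("set_level", "Alpelisib", 1, onset=2.0)],
            horizon=10.0,
            replicates=100,
            seed=8,
        )
        tc = run_ensemble(er_model, proto)
        for node in tc.node_names:
            occ = tc.occupancy_of(node)
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert tc.activities.min() >= 0.0 and tc.activities.max() <= 1.0

    def test_endpoint_matches_exact_absorption(self):
        # stochastic engine vs the exact Markov-chain absorption oracle
        model = random_model(
            GeneratorConfig(n_nodes=6, multilevel_fraction=0.4, max_levels=3, rule_bias=0.4, seed=4)
        )
        init = {v: False for v in model.indicators}
        atts, probs = exact_absorption(model, [], [(init, 1.0)])
        proto = Protocol(initial_states=[(init, 1.0)], horizon=80.0, replicates=2000, seed=9)
        tc = run_ensemble(model, proto)
        names = tc.variables
        lookup = {}
        for i, att in enumerate(atts):
            for s in att.states:
                lookup[tuple(1 if s[v] else 0 for v in names)] = i
        counts = np.zeros(len(atts))
        for row in tc.final_states:
            counts[lookup[tuple(int(x) for x in row)]] += 1
        mc = counts / tc.replicates
        se = np.sqrt(probs * (1 - probs) / tc.replicates)
        assert np.all(np.abs(mc - probs) <= 3 * np.maximum(se, 1e-3))

    def test_absorption_from_fixed_point(self, toy):
        state = toy.encode_levels({n: 1 for n in toy.node_names})
        proto = Protocol(initial_states=[(state, 1.0)], horizon=10.0, replicates=50, seed=10)
        tc = run_ensemble(toy, proto)
        assert (tc.activities == 1.0).all()


class TestClamps:
    def test_efficacy_clamp_flickers_at_rate(self, toy):
        # GF pinned ON but dropped with p_off = 0.5 each micro-step: the
        # endpoint activity of GF across replicates estimates 1 - p_off
        proto = Protocol(
            initial_states=[(toy.encode_levels({}), 1.0)],
            clamps=[Clamp("efficacy", "GF", 1, onset=0.0, p_off=0.5)],
            horizon=10.0,
            replicates=2000,
            seed=11,
        )
        tc = run_ensemble(toy, proto)
        assert tc.activity("GF")[-1] == pytest.approx(0.5, abs=0.05)

    def test_cap_clamp_pins_upper_levels(self, er_model, cancerous):
        proto = Protocol(
            initial_states=cancerous,
            clamps=[Clamp("cap_level", "pRb", 2, onset=0.0)],
            horizon=20.0,
            replicates=100,
            seed=12,
        )
        tc = run_ensemble(er_model, proto)
        assert tc.activity("pRb_2")[-1] == 0.0 and tc.activity("pRb_3")[-1] == 0.0

    def test_clamp_validation(self):
        with pytest.raises(ValueError, match="p_off"):
            Clamp("efficacy", "X", 1, p_off=1.5)
        with pytest.raises(ValueError, match="onset"):
            Clamp("set_level", "X", 1, onset=-1.0)
        with pytest.raises(ValueError, match="kind"):
            Clamp("pin", "X", 1)


class TestAddInhibitor:
    def test_adds_source_and_conjoins(self, toy):
        model = add_inhibitor(toy, "RTKi", [("RTK", None)])
        assert model.node("RTKi").is_source
        assert model.rules["RTK"] == And(Var("GF"), Not(Var("RTKi")))

    def test_guard_escape(self, toy):
        model = add_inhibitor(toy, "AKTi", [("AKT", Var("PIP3"))])
        rule = model.rules["AKT"]
        # inhibited without the guard, active when the guard holds
        assert rule.evaluate({"PIP3": True, "AKTi": True}) is True
        assert rule.evaluate({"PIP3": False, "AKTi": True, "PI3K": False}) is False

    def test_name_collision(self, toy):
        with pytest.raises(ValueError, match="collision"):
            add_inhibitor(toy, "GF", [("RTK", None)])
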