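"""Shipped model fixtures, named simulation protocols and validation suite.

Two fixtures are bundled as rule files:

``toy_rtk.model``
    the 9-node Boolean toy network of growth-factor/RTK signaling used
    to illustrate general-asynchronous dynamics, drug clamps and
    resistance overrides;

``bc_er_plus_synthetic.model``
    a *synthetic reconstruction* of the ER+/PIK3CA-mutant breast cancer
    network.  The original curated rule set is not redistributed here;
    this network is rebuilt from published mechanistic descriptions
    (including the verbatim AKT and ER_transcription rules) so that the
    documented qualitative behaviors emerge from the wiring: six
    cancerous steady states, the apoptosis/proliferation response to
    PI3K inhibition, PIM/SGK1-mediated resistance, and the
    ER/CDK4-6/mTORC1 synergies.  Quantitative endpoints of scenarios
    not used in its design may differ from the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .attractors import find_fixed_points
from .engine import Clamp, Protocol, add_inhibitor, run_ensemble
from .logic import LogicalModel, apply_context
from .outcomes import OutcomeWeights, summarize_endpoint
from .ruleformat import parse_model_text

__all__ = [
    "toy_rtk_model",
    "toy_with_inhibitors",
    "breast_cancer_model",
    "ER_PLUS_CONTEXT",
    "HER2_PLUS_CONTEXT",
    "DRUGS",
    "er_plus_context_model",
    "cancerous_ensemble",
    "outcome_weights",
    "ScenarioSpec",
    "named_protocols",
    "staggered_protocol",
    "table4_validation_suite",
]

DRUGS = (
    "Alpelisib",
    "Ipatasertib",
    "Fulvestrant",
    "Palbociclib",
    "Everolimus",
    "Trametinib",
    "Neratinib",
)

#: ER+/HER2- cell context: ER on, HER2/HER3 transcripts off, IGF1R present,
#: PBX1 on; PTEN, SGK1, PIM, PDK1 and mTORC2 overexpression absent.  The
#: BIM_T and BCL2_T sources stay free (either ON or OFF).
ER_PLUS_CONTEXT = {
    "IGF1": 1,
    "ER": 1,
    "HER2": 0,
    "HER3_T": 0,
    "IGF1R_T": 1,
    "PBX1": 1,
    "PTEN": 0,
    "SGK1_T": 0,
    "PIM": 0,
    "PDK1_T": 0,
    "mTORC2": 0,
}

HER2_PLUS_CONTEXT = {**ER_PLUS_CONTEXT, "HER2": 1, "HER3_T": 1}


def _load_fixture(name: str) -> LogicalModel:
    text = resources.files("bcnet.data").joinpath(name).read_text(encoding="utf-8")
    return parse_model_text(text)


def toy_rtk_model(tf_slow: bool = True) -> LogicalModel:
    """The 9-node Boolean toy RTK network.

    With ``tf_slow`` the Transcription Factors node keeps its slow class
    (1/5 the update probability of the signaling nodes); otherwise all
    nodes update with equal probability.
    """
    model = _load_fixture("toy_rtk.model")
    if not tf_slow:
        spec = model.node("TF")
        model.nodes[model.nodes.index(spec)] = type(spec)(
            name="TF", n_levels=2, update_class="fast", pathway=spec.pathway, is_source=False
        )
    return model


def toy_with_inhibitors(tf_slow: bool = True) -> LogicalModel:
    """Toy network plus RTKi (on RTK) and MEKi (on MEK/ERK) drug nodes."""
    model = toy_rtk_model(tf_slow=tf_slow)
    model = add_inhibitor(model, "RTKi", [("RTK", None)])
    model = add_inhibitor(model, "MEKi", [("MEK/ERK", None)])
    return model


def breast_cancer_model() -> LogicalModel:
    """The synthetic ER+ breast cancer network reconstruction (see module
    docstring); 49 biological nodes + 7 drug source nodes."""
    return _load_fixture("bc_er_plus_synthetic.model")


def er_plus_context_model(context: dict | None = None) -> LogicalModel:
    """Breast cancer model with the cell context fixed (drugs OFF).

    Drug source nodes are fixed OFF in the rules; protocols switch them on
    with set-level clamps, which override the context.
    """
    ctx = dict(ER_PLUS_CONTEXT if context is None else context)
    for drug in DRUGS:
        ctx.setdefault(drug, 0)
    return apply_context(breast_cancer_model(), ctx)


def cancerous_ensemble(model: LogicalModel) -> list:
    """Uniform distribution over the six cancerous steady states.

    The cancerous state is the set of no-drug fixed points with zero
    Apoptosis (high proliferation, survival signaling active); a count
    other than six signals a fixture error.
    """
    fps = find_fixed_points(model)
    cancerous = [a for a in fps if a.levels["Apoptosis"] == 0]
    if len(cancerous) != 6:
        raise ValueError(
            f"expected 6 cancerous steady states, found {len(cancerous)} (of {len(fps)} fixed points)"
        )
    p = 1.0 / len(cancerous)
    return [(a.states[0], p) for a in cancerous]


def outcome_weights(model: LogicalModel | None = None) -> OutcomeWeights:
    """Outcome-node weights shipped with the fixture."""
    return OutcomeWeights.from_model(breast_cancer_model() if model is None else model)


@dataclass
class ScenarioSpec:
    """A named simulation scenario: context + protocol + description."""

    name: str
    context: dict
    protocol: Protocol
    description: str = ""


def _alpelisib(onset: float = 2.0) -> Clamp:
    return Clamp(kind="set_level", node="Alpelisib", level=1, onset=onset)


def named_protocols(
    model: LogicalModel | None = None, replicates: int = 10_000, seed: int = 0
) -> dict:
    """The named scenarios: PI3K inhibition, PIM/SGK1 resistance contexts,
    the 90%-effective PIM variant, the screen baseline, and the staggered
    mTORC1i/PI3Ki timing protocol."""
    model = er_plus_context_model() if model is None else model
    ensemble = cancerous_ensemble(model)

    def proto(clamps, horizon=75.0, **kw):
        return Protocol(
            initial_states=ensemble,
            clamps=clamps,
            horizon=horizon,
            replicates=replicates,
            seed=seed,
            **kw,
        )

    scenarios = {
        "pi3ki": ScenarioSpec(
            "pi3ki",
            ER_PLUS_CONTEXT,
            proto([_alpelisib()]),
            "PI3K inhibition: Alpelisib ON from t=2, horizon 75",
        ),
        "pi3ki_pim": ScenarioSpec(
            "pi3ki_pim",
            ER_PLUS_CONTEXT,
            proto([Clamp("set_level", "PIM", 1, onset=0.0), _alpelisib()]),
            "constitutive PIM + PI3K inhibition",
        ),
        "pi3ki_sgk1_pdk1": ScenarioSpec(
            "pi3ki_sgk1_pdk1",
            ER_PLUS_CONTEXT,
            proto(
                [
                    Clamp("set_level", "SGK1_T", 1, onset=0.0),
                    Clamp("set_level", "PDK1_T", 1, onset=0.0),
                    Clamp("set_level", "SGK1", 1, onset=0.0),
                    _alpelisib(),
                ]
            ),
            "constitutive PDK1/SGK1 + PI3K inhibition",
        ),
        "pi3ki_pim90": ScenarioSpec(
            "pi3ki_pim90",
            ER_PLUS_CONTEXT,
            proto(
                [Clamp("efficacy", "PIM", 1, onset=0.0, p_off=0.10), _alpelisib()]
            ),
            "90%-effective PIM (dropped to OFF with p=0.10 per micro-step) + PI3K inhibition",
        ),
        "screen_baseline": ScenarioSpec(
            "screen_baseline",
            ER_PLUS_CONTEXT,
            proto([_alpelisib()], horizon=100.0),
            "baseline for perturbation screens: Alpelisib ON from t=2, horizon 100",
        ),
        "staggered_mtori_pi3ki": ScenarioSpec(
            "staggered_mtori_pi3ki",
            ER_PLUS_CONTEXT,
            proto(
                [Clamp("set_level", "Everolimus", 1, onset=0.0), _alpelisib()],
                horizon=120.0,
            ),
            "early mTORC1 inhibition (t=0) followed by PI3K inhibition (t=2), horizon 120",
        ),
    }
    return scenarios


def staggered_protocol(
    model: LogicalModel,
    mtori_onset: float,
    pi3ki_onset: float = 2.0,
    horizon: float = 120.0,
    replicates: int = 10_000,
    seed: int = 0,
) -> Protocol:
    """mTORC1-inhibitor onset varied relative to the PI3K inhibitor."""
    return Protocol(
        initial_states=cancerous_ensemble(model),
        clamps=[
            Clamp("set_level", "Everolimus", 1, onset=mtori_onset),
            _alpelisib(pi3ki_onset),
        ],
        horizon=horizon,
        replicates=replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# qualitative validation suite
# ---------------------------------------------------------------------------


def _apop0_ensemble(model):
    fps = [a for a in find_fixed_points(model) if a.levels["Apoptosis"] == 0]
    p = 1.0 / len(fps)
    return [(a.states[0], p) for a in fps]


def _crossing_time(tc, variable, threshold=0.5):
    act = tc.activity(variable)
    above = np.flatnonzero(act > threshold)
    return tc.grid[above[0]] if above.size else np.inf


def table4_validation_suite(
    model: LogicalModel | None = None, replicates: int = 2000, seed: int = 0
) -> list:
    """Directional checks of documented experimental/clinical outcomes.

    Each check is an inequality between simulated activities in two
    conditions; returns (check name, passed) pairs.
    """
    bc = breast_cancer_model() if model is None else model
    er_model = er_plus_context_model()
    her2_model = apply_context(bc, {**HER2_PLUS_CONTEXT, **{d: 0 for d in DRUGS}})
    weights = outcome_weights(bc)
    results = []

    def run(mdl, ensemble, clamps, horizon=75.0):
        return run_ensemble(
            mdl,
            Protocol(
                initial_states=ensemble,
                clamps=clamps,
                horizon=horizon,
                replicates=replicates,
                seed=seed,
            ),
        )

    # -- MEK inhibition in HER2+ cells raises HER2/HER3 heterodimer and PI3K
    her2_ens = _apop0_ensemble(her2_model)
    tc_no = run(her2_model, her2_ens, [])
    tc_meki = run(her2_model, her2_ens, [Clamp("set_level", "Trametinib", 1, onset=2.0)])
    hd_up = tc_meki.activity("HER2_HER3_2")[-1] > tc_no.activity("HER2_HER3_2")[-1] + 0.1
    results.append(("MEKi_HER2plus_raises_HER2_HER3", bool(hd_up)))
    pi3k_up = tc_meki.activity("PI3K_2")[-1] > tc_no.activity("PI3K_2")[-1] + 0.1
    results.append(("MEKi_HER2plus_raises_PI3K_activity", bool(pi3k_up)))

    # -- PI3K inhibition induces FOXO3, then upregulates ESR1 and HER3
    er_ens = cancerous_ensemble(er_model)
    tc = run(er_model, er_ens, [_alpelisib()])
    foxo3_up = tc.activity("FOXO3")[-1] > tc.activity("FOXO3")[0] + 0.5
    results.append(("PI3Ki_induces_FOXO3", bool(foxo3_up)))
    esr1_up = tc.activity("ESR1_2")[-1] > tc.activity("ESR1_2")[0] + 0.5
    her3_up = tc.activity("HER3")[-1] > tc.activity("HER3")[0] + 0.5
    results.append(("PI3Ki_upregulates_ESR1_and_HER3_transcripts", bool(esr1_up and her3_up)))
    foxo3_first = _crossing_time(tc, "FOXO3") < _crossing_time(tc, "ESR1_2")
    results.append(("FOXO3_rises_before_ESR1", bool(foxo3_first)))

    # -- high HER3 restores survivability under PI3K inhibition (HER2+)
    tc_ctrl = run(her2_model, her2_ens, [_alpelisib()])
    tc_her3 = run(
        her2_model, her2_ens, [Clamp("set_level", "HER3", 2, onset=0.0), _alpelisib()]
    )
    a_ctrl, _ = summarize_endpoint(tc_ctrl, weights)
    a_her3, _ = summarize_endpoint(tc_her3, weights)
    results.append(("HER3_high_restores_survivability_under_PI3Ki", bool(a_her3 < a_ctrl - 0.1)))

    return results
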