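# bcnet

Multi-level logical (discrete dynamic) modeling of signal transduction in
ER+/PIK3CA-mutant breast cancer: a general-asynchronous simulation engine,
exact attractor analysis, drug-clamp protocols, normalized
apoptosis/proliferation outcome scores, and exhaustive in-silico
perturbation screens for drug-resistance mechanisms and drug synergies.

## Who this is for

Systems biologists who want to simulate logic-based network models of
cancer signaling — where each protein/transcript is a node with a small
number of discrete activity levels and a Boolean regulatory rule — and ask
which sustained interventions (mutations, overexpression, drugs) change the
cell-fate outcomes.

## The model

A network node *i* carries a state variable σᵢ ∈ {0, …, Lᵢ−1} and a
regulatory function fᵢ written with AND/OR/NOT over the states of its
regulators.  Multi-level nodes are expanded into Boolean *indicator
variables*: `Node` means σ ≥ 1 and `Node_k` means σ ≥ k, each with its own
rule — so rules transcribe literally (e.g. `(PIP3 or PIP3_2)`), and a
state decodes back to a level by the highest active indicator.

Dynamics use **general-asynchronous updating**: at each micro-step one
indicator is chosen at random and set to its rule value,
σ_j(t) = f_j(Σ(t−1)).  Signaling ("fast") indicators are chosen with 5×
the probability of transcriptional ("slow") ones; time is scaled so one
unit equals the average time to update a slow indicator.  Averaging a
variable over N stochastic runs gives its *activity* aᵢ(t) ∈ [0, 1], the
fraction of simulated cells with the variable on.  Long-run behaviors are
attractors: fixed points f(x) = x (found exactly by constraint solving) or
complex attractors — terminal SCCs of the asynchronous state-transition
graph (enumerated by brute force for ≤ 20 indicators).

Drugs and mutations are **clamps**: `set_level` pins a node from an onset
time (σ_Alpelisib = ON at t = 2), `cap_level` bounds it (`pRb < 2`),
`rule_override` swaps a rule (f_RAS = ON), and `efficacy` pins with a
per-micro-step escape probability (a 90%-effective inhibitor).  The
multi-level outcome nodes Apoptosis and Proliferation are summarized as
weighted, [0, 1]-normalized scores of their ensemble level occupancies.

Two model fixtures ship with the package: a 9-node toy RTK cascade, and
`bc_er_plus_synthetic.model` — a **synthetic reconstruction** of an
ER+/PIK3CA-mutant breast cancer network (49 biological nodes, 13 sources,
7 drug nodes) rebuilt from published mechanistic descriptions; it is not
the original curated rule set, and its fixture header documents the
outcome-weight calibration.

## Worked example

```python
from bcnet import models
from bcnet.engine import run_ensemble
from bcnet.outcomes import summarize_endpoint, score_timecourse

model = models.er_plus_context_model()          # ER+/HER2- context, drugs off
weights = models.outcome_weights()
scenario = models.named_protocols(model, replicates=2000, seed=1)["pi3ki"]
tc = run_ensemble(model, scenario.protocol)     # Alpelisib ON from t=2, horizon 75
apop, prolif = summarize_endpoint(tc, weights)
prolif_t = score_timecourse(tc, "Proliferation", weights)
print(f"Apoptosis_norm = {apop:.2f}, Proliferation_norm = {prolif:.2f}")
print(f"proliferation: initial {prolif_t[0]:.2f}, dip {prolif_t[3:].min():.2f}, final {prolif_t[-1]:.2f}")
```

prints

```
Apoptosis_norm = 0.70, Proliferation_norm = 0.25
proliferation: initial 0.75, dip 0.21, final 0.25
```

Read: before the drug the cancerous ensemble (six steady states,
Proliferation 3–4, Apoptosis 0) scores (0.00, 0.75).  PI3K inhibition
drives apoptosis to 0.70 — the mixture of Apoptosis level 2 (cells that
started with BCL2 on, 2/3 of the ensemble) and level 3 (BCL2 off) — while
proliferation first dips (fast loss of AKT/MAPK/mTORC1 signaling) and then
rebounds to level 2 (0.25) as the slow FOXO3→ESR1/FOXA1→ER transcriptional
program engages.

The numbered scripts under `analysis/` run the full story — toy-network
dynamics, cancerous attractors, the PI3K-inhibition response with
PIM/SGK1 resistance, the single-node resistance and synergy screens, and
the staggered mTORC1i/PI3Ki timing experiment — and write their tables
under `results/`.  The `bcnet` CLI (`simulate`, `attractors`, `screen`)
exposes the same operations on rule files.

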