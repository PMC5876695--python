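# Methods

## Model representation

A logical model is a set of nodes, each with `n_levels ≥ 2` discrete
states, a kinetic class (`fast` for signaling events, `slow` for
transcription/translation), a pathway tag, and a source flag.  A node
with L levels is expanded into L−1 Boolean indicator variables (`X`,
`X_2`, …, `X_{L−1}`, reading "level ≥ k"), each with exactly one Boolean
rule over indicators.  We deliberately do **not** force the staircase
property (`X_2 ⇒ X`): rules written over indicators (e.g. the defensive
`(PIP3 or PIP3_2)` pattern) may transiently produce non-staircase states
under asynchronous updating, and decoding uses the max-index convention
(the level is the highest active indicator).  On staircase-consistent
states this equals the ordinary multi-level reading, and the engine's
trajectories from staircase states agree under both conventions for
monotone rules; the max-index choice only matters on defensive-OR rules
during transients.

Source nodes encode cell context (receptor status, genotype, drug
presence) and must be self-contained: their rules reference only their
own indicators (`f_X = X`) or constants.  Context application replaces
source rules by constants; drug protocols then override the drug sources
with clamps.

## General-asynchronous dynamics and scaled time

One indicator variable is updated per micro-step, selected with
probability proportional to its weight; fast indicators weigh 5, slow
weigh 1 (the 5:1 ratio is a deliberate understatement of the real
signaling-vs-transcription timescale gap, kept for comparability of
timecourses).  Each indicator inherits its node's class weight; we update
one *indicator* (not one whole node) per micro-step — the simplest
reading of the Boolean expansion, and the choice is isolated behind
`UpdateWeights`/`scaled_time` should the alternative be needed.

Time is reported in scaled units: `t = micro_steps × p_slow`, where
`p_slow` is the selection probability of one slow indicator
(= 1/(5·n_fast + n_slow) at default weights).  One unit is therefore the
expected waiting time for a given slow variable's update.  The inverse
map rounds up to the next micro-step.  Models with no slow class fall
back to the slowest class present, with a warning.  Horizons follow the
protocol conventions: 75 units for timecourses, 100 for screens, up to
120 for staggered-timing runs — long enough for all shipped scenarios to
satisfy the endpoint-convergence check (< 0.01 score movement over the
trailing 10 units).

## Clamps

* `set_level v`: pins indicators k ≤ v ON and k > v OFF, from onset to
  offset, enforced on the state immediately at onset and after every
  update (so a selected pinned variable cannot escape).
* `cap_level b`: pins indicators k ≥ b OFF, leaving lower levels free.
* `rule_override`: swaps one indicator's rule; the state changes only
  when that indicator is next selected.  This reproduces the distinction
  between setting a drug node's *state* and introducing a *mutation*.
* `efficacy p_off`: after each micro-step the clamped node is dropped to
  level 0 with probability `p_off`, otherwise pinned at its level; "time
  step" is taken as micro-step.  A 90%-effective target has
  `p_off = 0.10`.

## Ensembles, outcomes and reproducibility

`run_ensemble` runs N independent trajectories through a numba-compiled
stack machine over byte-compiled rules; activities and per-node level
occupancies are accumulated on the sampling grid (recording the state at
the last micro-step not exceeding each grid point).  Replicate r uses a
deterministic child seed of the protocol seed, so every ensemble, screen
and analysis script is bit-reproducible per seed.  The pure-Python
`ga_step`/`run_trajectory` path implements the same semantics and is
cross-checked against the kernel through exact absorption probabilities
(below).

Outcome scores are occupancy-weighted averages of the Apoptosis (levels
0–3) and Proliferation (levels 0–4) nodes, with weights anchored at 0
and 1.  The shipped weights are calibrated to the published anchor
values: Proliferation [0, 0.125, 0.25, 0.5, 1] (levels 1/2/3 score
0.125/0.25/0.50) and Apoptosis [0, 0.25, 0.55, 1] (level 2 chosen so the
2:1 BCL2-on:off steady-state mixture under PI3K inhibition scores 0.70).
Endpoints are the final grid point, guarded by the convergence check,
not a tail average — the reference scenarios stabilize.

## Attractors

Fixed points are enumerated exactly for models of any size by constraint
propagation: any indicator whose rule value is determined by the partial
assignment is forced (a fixed point needs x_v = f_v(x)); contradictions
prune; remaining indicators are branched on.  Every reported attractor of
the shipped breast cancer network is a fixed point.  Full asynchronous
attractors (terminal SCCs of the state-transition graph, including
oscillations such as the adaptive RTK-feedback cycle that appears in the
HER2+ context under PI3K inhibition) are enumerated by brute force up to
20 indicator variables using vectorized rule evaluation and
`scipy.sparse.csgraph` strong components.  Stable-motif/succession-diagram
machinery is out of scope; the fixed-point solver plus the exhaustive STG
reproduce all analyses here.  Attractors are canonically ordered by their
decoded level vectors.

The exhaustive STG also yields an independent oracle for the stochastic
engine: the weighted Markov chain of the dynamics is built explicitly and
absorption probabilities into each attractor are solved as a sparse
linear system.  The test suite requires Monte-Carlo basin fractions at
2,000 replicates to match these exact values within 3 standard errors on
random models, and the fixed-point solver to set-equal the singleton
terminal SCCs on 50 random models.

## Screens

Perturbations are sustained clamps from t = 0 (before the drug at t = 2,
matching the resistance-scenario convention): every set-level to every
level of every node, plus caps below each level ≥ 2.  Single and unordered
double combinations are enumerated; each runs with a child seed over the
horizon-100 Alpelisib baseline.  Resistance rows lower apoptosis and/or
raise proliferation relative to the drug-alone control by more than 3
Monte-Carlo standard errors; synergy is the reverse.  Equivalence
grouping is behavioral: two rows merge when their endpoint scores agree
and their final activity vectors agree outside the indicator columns of
their own clamped nodes (a clamp trivially differs there), elementwise
within 3 pooled binomial standard errors.  Structural network-equivalence
detection is not attempted.  The mechanism tag of a row is the pathway
tag of its target nodes.

## The ER+ network fixture is a synthetic reconstruction

The original curated rule set for the ER+/PIK3CA-mutant network is not
redistributed in this package.  `bc_er_plus_synthetic.model` was rebuilt
from published mechanistic descriptions: the AKT and ER-transcription
rules are transcribed verbatim; receptor, PI3K/AKT, MAPK, mTORC1, ER,
cell-cycle and apoptosis wiring encode the described interactions (PIM
shares PRAS40/BAD/p21-p27/FOXO3 with AKT but not TSC or KMT2D; SGK1
shares TSC and FOXO3; mTORC1 activates when either brake is released;
MCL1 follows mTORC1-dependent translation; the E2F top level
self-sustains through the cyclin-E positive feedback, which creates the
Proliferation 3-vs-4 bistability of the cancerous state).  The designed
behaviors — six cancerous steady states with the BIM/BCL2 priming
pattern, the (0.70, 0.25) PI3K-inhibition endpoint with a transient
proliferation dip, full PIM resistance vs partial SGK1 resistance, the
ER/CDK4-6/BCL2 synergy anchors, and the qualitative clinical-outcome
checks — emerge from this wiring and are what the tests assert.

Known reconstruction differences, accepted rather than tuned away: the
no-drug Proliferation_norm is 0.75 (uniform over the six steady states
with the calibrated weights); Fulvestrant scores (0.70, 0.00) rather than
showing an extra apoptotic increment; Everolimus matches the control
apoptosis at endpoint, so the mTORC1i synergy appears only through the
timing analysis, where early mTORC1 inhibition attains the same maximum
apoptosis as forcing MCL1 off but not a strict excess over late
inhibition (the apoptosis indicators carry no kinetic priming memory).

## Synthetic model generator

`random_model` draws node classes, level counts, sources and random
truth-table rules (converted to DNF), guaranteeing coverage of
non-monotone logic; generated models always validate and serialize
through the standard rule dialect.  The generator emulates the structural
features of the curated network — mixed Boolean/multi-level nodes,
fast/slow classes, self-sustaining sources — but not its biology: pathway
tags are arbitrary and rules are unconstrained, so passing property tests
demonstrates engine correctness (semantics, absorption, reproducibility),
not biological validity of any particular network.

## Numerical and degenerate-input choices

Selection uses a cumulative-weight binary search; byte-code evaluation
uses a fixed 64-deep stack (ample for the shipped rules).  Clamp onsets
convert to micro-steps by rounding up; grid points record the last
micro-step not exceeding them; grid point 0 reports the initial ensemble
after onset-0 pins.  Absorption linear solves clip round-off outside
[0, 1].  Ties in screen rankings break lexicographically by perturbation
label; attractor order is lexicographic on decoded levels.  Empty
perturbations are the screen control; protocols validate that initial
probabilities sum to 1 and grids stay within the horizon.

## Problem sizes used in the shipped runs

Tests run ensembles at 100–2,000 replicates with Monte-Carlo-aware
tolerances; the acceptance script uses 2,000 replicates for endpoint
scores and 1,000 for screen rows and timing maxima; the analysis scripts
default to 1,000–2,000 and accept `--replicates` for the 10,000-replicate
convention of the reference tables.
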