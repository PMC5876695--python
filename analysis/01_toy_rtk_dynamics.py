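#!/usr/bin/env python
"""Toy RTK network: activation cascade, drug inhibition, resistance.

Reproduces the four illustrative scenarios on the 9-node toy network —
growth-factor activation, RTK-inhibitor reversal, RAS-mutation
resistance, and MEK-inhibitor rescue — and writes the ensemble activity
timecourses to results/toy_timecourses.tsv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from bcnet import models
from bcnet.engine import Clamp, Protocol, run_ensemble
from bcnet.io import provenance_header, timecourse_table, write_table
from bcnet.logic import Const

warnings.filterwarnings("ignore", message="no slow variables")

parser = argparse.ArgumentParser()
parser.add_argument("--replicates", type=int, default=2000)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

toy = models.toy_with_inhibitors()
gf_only = toy.encode_levels({"GF": 1})
with_rtki = toy.encode_levels({"GF": 1, "RTKi": 1})

scenarios = {
    "gf_on": ([(gf_only, 1.0)], []),
    "rtki_at_20": ([(gf_only, 1.0)], [Clamp("set_level", "RTKi", 1, onset=20.0)]),
    "ras_mutation_at_20": (
        [(with_rtki, 1.0)],
        [Clamp("set_level", "RTKi", 1), Clamp("rule_override", "RAS", onset=20.0, expr=Const(True))],
    ),
    "meki_at_20": (
        [(with_rtki, 1.0)],
        [
            Clamp("set_level", "RTKi", 1),
            Clamp("rule_override", "RAS", expr=Const(True)),
            Clamp("set_level", "MEKi", 1, onset=20.0),
        ],
    ),
}

frames = []
for name, (initial, clamps) in scenarios.items():
    proto = Protocol(
        initial_states=initial, clamps=clamps, horizon=60.0, replicates=args.replicates, seed=args.seed
    )
    tc = run_ensemble(toy, proto)
    df = timecourse_table(tc)
    df.insert(0, "scenario", name)
    frames.append(df)
    tf = tc.activity("TF")
    print(f"{name:22s} TF activity: start {tf[0]:.2f} @t20 {tf[20]:.2f} end {tf[-1]:.2f}")

write_table(
    pd.concat(frames, ignore_index=True),
    args.out / "toy_timecourses.tsv",
    header=provenance_header(model=toy, seed=args.seed, replicates=args.replicates),
)
print(f"wrote {args.out / 'toy_timecourses.tsv'}")
print(
    "Summary: GF switches the cascade fully on; the RTK inhibitor reverses it; "
    "a RAS-activating mutation resists the RTK inhibitor (all nodes except RTK back on); "
    "adding the MEK inhibitor drives the outcome node TF back to zero."
)
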