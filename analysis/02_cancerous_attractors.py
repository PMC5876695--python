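#!/usr/bin/env python
"""ER+ network: exact steady states of the no-drug cancerous context.

Enumerates all fixed points of the ER+/HER2- context by constraint
solving and writes them to results/cancerous_attractors.tsv.  The
apoptosis-free subset (the cancerous ensemble used as the initial
condition of every drug protocol) should number exactly six:
Proliferation 3 or 4 (E2F 2 or 3) crossed with the three BIM/BCL2
priming combinations in which BCL2 neutralizes any active BIM.
"""

import argparse
from pathlib import Path

from bcnet import models
from bcnet.attractors import find_fixed_points
from bcnet.io import attractor_table, provenance_header, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

model = models.er_plus_context_model()
fps = find_fixed_points(model)
cancerous = [a for a in fps if a.levels["Apoptosis"] == 0]

print(f"{len(fps)} fixed points in the ER+ no-drug context; {len(cancerous)} cancerous (Apoptosis = 0)")
for att in fps:
    lv = att.levels
    print(
        f"  Proliferation={lv['Proliferation']} E2F={lv['E2F']} "
        f"BIM={lv['BIM']} BCL2={lv['BCL2']} Apoptosis={lv['Apoptosis']}"
    )

write_table(
    attractor_table(fps),
    args.out / "cancerous_attractors.tsv",
    header=provenance_header(model=model),
)
print(f"wrote {args.out / 'cancerous_attractors.tsv'}")
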