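# Toy RTK signaling network: growth-factor -> RTK -> RAS/PI3K -> MAPK/AKT -> TF.
# 9 Boolean nodes; the growth factor is a self-sustaining source.
# The TF node is declared slow so that transcription lags signaling when
# the 5:1 fast:slow update-weight ratio is applied.

node GF levels=2 class=fast pathway=RTK source
node RTK levels=2 class=fast pathway=RTK
node RAS levels=2 class=fast pathway=MAPK
node PI3K levels=2 class=fast pathway=PI3K
node BRAF levels=2 class=fast pathway=MAPK
node PIP3 levels=2 class=fast pathway=PI3K
node MEK/ERK levels=2 class=fast pathway=MAPK
node AKT levels=2 class=fast pathway=AKT
node TF levels=2 class=slow pathway=ER

rule GF = GF
rule RTK = GF
rule RAS = RTK
rule PI3K = RTK or RAS
rule BRAF = RAS
rule PIP3 = PI3K
rule MEK/ERK = BRAF
rule AKT = PIP3
rule TF = AKT and MEK/ERK
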