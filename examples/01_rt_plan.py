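"""Plan reverse-transcription reactions from replicate RNA concentrations.

Six samples measured in triplicate; the kit needs 4 ul SuperMix and 1 ul
gDNA remover per ug of RNA, we load 2 ug into a 40 ul reaction, and water
fills the remainder.
"""

import pandas as pd

from qpcrkit import RTRecipe, plan_rt

conc = pd.DataFrame([
    {"sample": s, "conc": c}
    for s, reps in {
        "1": [160.4, 160.4, 160.4],
        "2": [163.0, 163.0, 164.0],
        "3": [182.0, 183.0, 182.71],
    }.items()
    for c in reps
])

recipe = RTRecipe(components={"SuperMix": 4.0, "gDNARemover": 1.0},
                  rna_mass_ug=2.0, total_volume_ul=40.0)
plan = plan_rt(conc, recipe)
print(plan.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# Each row: ul of RNA delivering 2 ug at that sample's mean concentration,
# fixed kit volumes (8 + 2 ul at 2 ug), and water topping up to 40 ul.
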