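"""Sweep: how much IOP increase does a suture buy, across starting IOPs?

Reproduces the structure of the design charts: below the episcleral venous
pressure the increase is a constant (trabecular pathway shut, no relief
valve); above it, the stiffer bleb implied by a higher starting IOP means
the implant carries less flow and the suture matters less and less.
"""

import numpy as np

from sutureflow import Placement, iop_increase_sweep
from sutureflow.presets import aqueous_humor, baseline_eye, narrow_implant

df = iop_increase_sweep(
    baseline_eye(), narrow_implant(), Placement.CONCENTRIC,
    p_c1_grid=np.arange(2.0, 18.1, 2.0), d_s_grid=[35.0],
    fluid=aqueous_humor(),
)
df["increase"] = df.p_c2_mmHg - df.p_c1_mmHg
print(df.to_string(index=False,
                   formatters={"increase": "{:.3f}".format,
                               "p_c2_mmHg": "{:.2f}".format}))
print()
print("Constant +2.1 mm Hg plateau while both states sit below 10.5 mm Hg;")
print("through the mixed window the trabecular pathway reopens, and beyond")
print("it the benefit of the same suture decays with the starting IOP.")
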