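"""Pressure drop across an open Baerveldt drainage tube.

Even if the tube carried the eye's entire ciliary inflow, the wide 305 um
bore drops almost no pressure — which is why the IOP after implantation is
essentially the bleb pressure, and why a thin suture barely changes it.
"""

from sutureflow import tube_pressure_drop
from sutureflow.presets import aqueous_humor, baerveldt_implant, narrow_implant

dp = tube_pressure_drop(2.0, baerveldt_implant(), fluid=aqueous_humor())
print(f"Open 305 um x 11 mm tube at 2 ul/min: dp = {dp:.5f} mm Hg")
print("  -> far below 0.01 mm Hg: the IOP rides on the bleb pressure.")

dp_narrow = tube_pressure_drop(2.0, narrow_implant(), fluid=aqueous_humor())
print(f"Same flow through a 100 um bore:      dp = {dp_narrow:.3f} mm Hg")
print("  -> bore diameter enters as D^4, so narrowing 3x raises the drop ~87x.")
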