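"""Shape factor of the sutured tube cross-section, both suture placements.

S corrects the circular-pipe Poiseuille law for the annular cross-section
left by a suture of diameter D_s in a bore D_i (kappa = D_s/D_i).  A
wall-touching suture leaves a crescent-shaped gap and always offers less
resistance than the same suture held on the axis.
"""

import numpy as np

from sutureflow import concentric_shape_factor, shape_factor

print("kappa   S_concentric   S_wall_touching")
for kappa in np.linspace(0.0, 0.9, 10):
    sc = concentric_shape_factor(kappa)
    sw = shape_factor(kappa, "wall_touching")
    print(f"{kappa:4.1f}    {sc:10.4f}    {sw:12.4f}")
print()
print("The wall-touching value is below the concentric one at every kappa:")
print("a free suture that settles on the wall restricts flow less than a")
print("perfectly centred one, so sizing a suture from the concentric curve")
print("underestimates the diameter actually needed.")
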