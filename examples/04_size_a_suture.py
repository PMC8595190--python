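"""Inverse problem: size the suture that lifts a hypotonic IOP to a target.

Given the measured post-implant IOP and the desired IOP, the bleb pressure
is eliminated (assuming the bleb's effective resistance is unchanged by the
second intervention) and the required tube-resistance ratio is inverted for
the suture diameter.  The result is an upper bound: scarring of the bleb or
bending of the suture would add resistance beyond this model.
"""

from sutureflow import CorrectionProblem, Placement, suture_diameter_for_target
from sutureflow.presets import aqueous_humor, baseline_eye, narrow_implant

for placement in (Placement.CONCENTRIC, Placement.WALL_TOUCHING):
    sol = suture_diameter_for_target(CorrectionProblem(
        eye=baseline_eye(),
        geometry=narrow_implant(),
        p_c1_mmhg=5.0,
        p_c2_target_mmhg=7.0,
        placement=placement,
        fluid=aqueous_humor(),
    ))
    print(f"{placement.value:14s}: required resistance ratio = "
          f"{sol.resistance_ratio_required:.3f}, D_s <= {sol.d_s_um:.1f} um")
print()
print("Raising the IOP from 5 to 7 mm Hg in a 100 um tube needs a ~34 um")
print("coaxial suture; a suture resting on the wall must be thicker to do")
print("the same job because the crescent gap it leaves drains more easily.")
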