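"""Reference parameter sets.

The baseline values are the ones commonly used for the human eye in the
aqueous-humor-dynamics literature: viscosity 0.75 mPa·s, episcleral venous
pressure 10.5 mm Hg, bleb reference pressure 0, ciliary inflow 2 µl/min of
which 15% leaves by the uveoscleral route (so Q_0 = 1.7 µl/min), pre-surgery
IOP 35 mm Hg.  The Baerveldt implant is the common non-valved device: bore
305 µm, tube length 11 mm; the 100 µm narrow-bore geometry illustrates a
diameter at which a thin suture gives clinically useful IOP control.
"""

from __future__ import annotations

from .geometry import FluidProperties, ImplantGeometry
from .steady_state import EyeParameters


def baseline_eye() -> EyeParameters:
    """Baseline eye: p_g=35, p_ev=10.5, p_r=0 mm Hg; Q_cb=2 µl/min, 15% uveoscleral."""
    return EyeParameters(
        p_g_mmhg=35.0,
        p_ev_mmhg=10.5,
        p_r_mmhg=0.0,
        q_cb_ul_min=2.0,
        uveoscleral_fraction=0.15,
    )


def aqueous_humor() -> FluidProperties:
    """Aqueous humor at body temperature: 0.75 mPa·s."""
    return FluidProperties(viscosity_mpa_s=0.75)


def baerveldt_implant() -> ImplantGeometry:
    """Baerveldt drainage tube: D_i = 305 µm, L_v = 11 mm."""
    return ImplantGeometry(inner_diameter_um=305.0, length_mm=11.0)


def narrow_implant() -> ImplantGeometry:
    """Narrow-bore tube (D_i = 100 µm, L_v = 11 mm) where suture control works."""
    return ImplantGeometry(inner_diameter_um=100.0, length_mm=11.0)
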