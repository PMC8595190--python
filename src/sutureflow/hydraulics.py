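"""Generalized Hagen–Poiseuille law for the implant tube.

Fully developed Stokes flow in the tube (Reynolds number << 1, entrance
length negligible) gives a linear pressure-drop/flow relation

    dp = R * Q,     R = 128 * S * L_v * mu / (pi * D_h**4),

with the shape factor S and hydraulic diameter D_h supplied by
:mod:`sutureflow.shape_factor` (S = 1, D_h = D_i for an open tube).
Computation is in SI internally; interfaces are in clinical units.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .geometry import CrossSection, FluidProperties, ImplantGeometry, SutureConfig
from .shape_factor import Resolution, shape_factor
from .units import mmhg_to_pa, pa_to_mmhg, ul_min_to_m3_s


def tube_hydraulic_resistance_si(
    geometry: ImplantGeometry,
    suture: Optional[SutureConfig] = None,
    fluid: FluidProperties = FluidProperties(),
    resolution: Resolution = Resolution(),
) -> float:
    """Tube resistance R in Pa per (m^3/s)."""
    section = CrossSection.from_implant(geometry, suture)
    s = 1.0 if section.suture_diameter_um == 0 else shape_factor(
        section.kappa, section.placement, resolution
    )
    dh = section.hydraulic_diameter_um() * 1e-6
    return 128.0 * s * geometry.length_m * fluid.viscosity_pa_s / (np.pi * dh**4)


def tube_hydraulic_resistance(
    geometry: ImplantGeometry,
    suture: Optional[SutureConfig] = None,
    fluid: FluidProperties = FluidProperties(),
    resolution: Resolution = Resolution(),
) -> float:
    """Tube resistance in clinical units: mm Hg per (µl/min)."""
    r_si = tube_hydraulic_resistance_si(geometry, suture, fluid, resolution)
    return pa_to_mmhg(r_si * ul_min_to_m3_s(1.0))


def tube_pressure_drop(
    flow_rate_ul_min: float,
    geometry: ImplantGeometry,
    suture: Optional[SutureConfig] = None,
    fluid: FluidProperties = FluidProperties(),
    resolution: Resolution = Resolution(),
) -> float:
    """Pressure drop (mm Hg) across the implant at the given flow (µl/min)."""
    if flow_rate_ul_min < 0:
        raise ValueError("flow rate must be >= 0")
    r_si = tube_hydraulic_resistance_si(geometry, suture, fluid, resolution)
    return pa_to_mmhg(r_si * ul_min_to_m3_s(flow_rate_ul_min))
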