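"""Lumped steady-state model of aqueous outflow after implant surgery.

The anterior chamber is a node at pressure ``p_c`` (the IOP) fed by the
ciliary inflow and drained by two parallel branches:

* the trabecular meshwork / Schlemm's canal, a linear resistance discharging
  to the episcleral venous pressure ``p_ev``; it carries flow only while
  ``p_c > p_ev`` (trabecular-open regime) and is calibrated from the
  pre-surgery state, R_tm = (p_g - p_ev) / Q_0;
* the implant tube in series with the filtration bleb, which discharges to a
  reference pressure ``p_r`` through an effective bleb resistance R_b.

``Q_0`` is the ciliary inflow minus the pressure-independent uveoscleral
fraction.  Mass balance at the node plus the two branch laws yield the
post-implant IOP in closed form in each regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InfeasibleError
from .geometry import CrossSection, FluidProperties, ImplantGeometry, SutureConfig
from .shape_factor import Resolution, shape_factor
from .units import mmhg_to_pa, pa_to_mmhg, ul_min_to_m3_s, m3_s_to_ul_min


class Regime(str, Enum):
    TRABECULAR_OPEN = "trabecular_open"
    TRABECULAR_CLOSED = "trabecular_closed"


@dataclass(frozen=True)
class EyeParameters:
    """Physiological constants of one eye, in clinical units.

    p_g is the pre-surgery IOP (the calibration point of the trabecular
    resistance); p_ev the episcleral venous pressure; p_r the reference
    pressure the bleb discharges to; Q_cb the ciliary inflow of which a
    pressure-independent ``uveoscleral_fraction`` bypasses both outflow
    branches.
    """

    p_g_mmhg: float = 35.0
    p_ev_mmhg: float = 10.5
    p_r_mmhg: float = 0.0
    q_cb_ul_min: float = 2.0
    uveoscleral_fraction: float = 0.15

    def __post_init__(self):
        if not (self.p_g_mmhg > self.p_ev_mmhg >= 0):
            raise ValueError("need p_g > p_ev >= 0")
        if self.p_r_mmhg < 0:
            raise ValueError("p_r must be >= 0")
        if self.q_cb_ul_min <= 0:
            raise ValueError("ciliary inflow must be > 0")
        if not (0 <= self.uveoscleral_fraction < 1):
            raise ValueError("uveoscleral fraction must be in [0, 1)")

    @property
    def q0_ul_min(self) -> float:
        """Flow available to the pressure-driven outflow branches (µl/min)."""
        return self.q_cb_ul_min * (1.0 - self.uveoscleral_fraction)

    @property
    def q0_si(self) -> float:
        return ul_min_to_m3_s(self.q0_ul_min)

    @property
    def trabecular_resistance_mmhg_per_ul_min(self) -> float:
        """Pre-surgery calibration (p_g - p_ev) / Q_0; flow-rate independent."""
        return (self.p_g_mmhg - self.p_ev_mmhg) / self.q0_ul_min


@dataclass(frozen=True)
class BlebModel:
    """Effective hydraulic resistance of the filtration bleb."""

    resistance_mmhg_per_ul_min: float

    def __post_init__(self):
        if self.resistance_mmhg_per_ul_min <= 0:
            raise ValueError("bleb resistance must be > 0")


@dataclass(frozen=True)
class SurgeryState:
    """One steady state of the post-implant outflow network."""

    p_c_mmhg: float
    p_b_mmhg: float
    q_i_ul_min: float
    q_tm_ul_min: float
    regime: Regime
    at_regime_boundary: bool = False


def _tube_conductance_si(
    geometry: ImplantGeometry,
    suture: Optional[SutureConfig],
    fluid: FluidProperties,
    resolution: Resolution,
) -> float:
    """G = pi D_h^4 / (128 S L_v mu) in (m^3/s)/Pa."""
    section = CrossSection.from_implant(geometry, suture)
    s = 1.0 if section.suture_diameter_um == 0 else shape_factor(
        section.kappa, section.placement, resolution
    )
    dh = section.hydraulic_diameter_um() * 1e-6
    return np.pi * dh**4 / (128.0 * s * geometry.length_m * fluid.viscosity_pa_s)


def post_implant_state(
    eye: EyeParameters,
    geometry: ImplantGeometry,
    suture: Optional[SutureConfig] = None,
    bleb_pressure_mmhg: float = 0.0,
    fluid: FluidProperties = FluidProperties(),
    resolution: Resolution = Resolution(),
) -> SurgeryState:
    """Steady state of the outflow network at a prescribed bleb pressure.

    Solves the trabecular-open balance first and accepts it iff the
    resulting IOP exceeds p_ev; otherwise the trabecular branch is shut and
    the whole Q_0 passes through the implant.  At exact equality both
    branches give p_c = p_ev (the model is continuous there); the state is
    then flagged and labelled trabecular_closed by the "<=" convention.
    """
    if bleb_pressure_mmhg < 0:
        raise ValueError("bleb pressure must be >= 0")
    g = _tube_conductance_si(geometry, suture, fluid, resolution)
    pg = mmhg_to_pa(eye.p_g_mmhg)
    pev = mmhg_to_pa(eye.p_ev_mmhg)
    pb = mmhg_to_pa(bleb_pressure_mmhg)
    q0 = eye.q0_si

    # trabecular-open balance
    pc_open = (g * pb * (pg - pev) + pg * q0) / (g * (pg - pev) + q0)
    if pc_open > pev:
        qi = g * q0 * (pg - pb) / (g * (pg - pev) + q0)
        if qi < 0:
            raise InfeasibleError(
                "bleb pressure exceeds the achievable IOP: implant flow would "
                "be negative"
            )
        qtm = q0 - qi
        return SurgeryState(
            p_c_mmhg=pa_to_mmhg(pc_open),
            p_b_mmhg=bleb_pressure_mmhg,
            q_i_ul_min=m3_s_to_ul_min(qi),
            q_tm_ul_min=m3_s_to_ul_min(qtm),
            regime=Regime.TRABECULAR_OPEN,
        )

    # trabecular-closed: the implant carries all of Q_0
    pc_closed = pb + q0 / g
    boundary = pc_closed > pev  # only possible in a vanishing numerical band
    pc = pev if boundary else pc_closed
    return SurgeryState(
        p_c_mmhg=pa_to_mmhg(pc),
        p_b_mmhg=bleb_pressure_mmhg,
        q_i_ul_min=m3_s_to_ul_min(q0),
        q_tm_ul_min=0.0,
        regime=Regime.TRABECULAR_CLOSED,
        at_regime_boundary=bool(boundary),
    )


def design_hydraulic_diameter(
    eye: EyeParameters,
    length_mm: float,
    shape_factor_value: float,
    target_p_c_mmhg: float,
    bleb_pressure_mmhg: float,
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Hydraulic diameter (µm) whose steady state hits the target IOP.

    The regime is chosen by the target against p_ev; the admissible target
    window is (p_b, p_g) in the open regime and (p_b, p_ev] in the closed
    one.
    """
    pg, pev = eye.p_g_mmhg, eye.p_ev_mmhg
    pc, pb = target_p_c_mmhg, bleb_pressure_mmhg
    if pc <= pb:
        raise InfeasibleError(
            f"target IOP {pc} mm Hg must exceed the bleb pressure {pb} mm Hg"
        )
    if pc >= pg:
        raise InfeasibleError(
            f"target IOP {pc} mm Hg must lie below the pre-surgery IOP {pg} mm Hg"
        )
    lv = length_mm * 1e-3
    mu = fluid.viscosity_pa_s
    q0 = eye.q0_si
    num = 128.0 * shape_factor_value * lv * q0 * mu
    if pc > pev:
        dh4 = num * mmhg_to_pa(pg - pc) / (
            np.pi * mmhg_to_pa(pc - pb) * mmhg_to_pa(pg - pev)
        )
    else:
        dh4 = num / (np.pi * mmhg_to_pa(pc - pb))
    return float(dh4**0.25 * 1e6)


def design_length(
    eye: EyeParameters,
    hydraulic_diameter_um: float,
    shape_factor_value: float,
    target_p_c_mmhg: float,
    bleb_pressure_mmhg: float,
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Implant length (mm) whose steady state hits the target IOP."""
    pg, pev = eye.p_g_mmhg, eye.p_ev_mmhg
    pc, pb = target_p_c_mmhg, bleb_pressure_mmhg
    if pc < pb:
        raise InfeasibleError(
            f"target IOP {pc} mm Hg must be at or above the bleb pressure {pb} mm Hg"
        )
    if pc >= pg:
        raise InfeasibleError(
            f"target IOP {pc} mm Hg must lie below the pre-surgery IOP {pg} mm Hg"
        )
    dh = hydraulic_diameter_um * 1e-6
    mu = fluid.viscosity_pa_s
    q0 = eye.q0_si
    den = 128.0 * shape_factor_value * q0 * mu
    if pc > pev:
        lv = np.pi * dh**4 * mmhg_to_pa(pg - pev) * mmhg_to_pa(pc - pb) / (
            den * mmhg_to_pa(pg - pc)
        )
    else:
        lv = np.pi * dh**4 * mmhg_to_pa(pc - pb) / den
    return float(lv * 1e3)


def bleb_resistance_from_state(state: SurgeryState, p_r_mmhg: float = 0.0) -> BlebModel:
    """Bleb resistance inferred from one measured steady state.

    R_b = (p_b - p_r) / Q_i; undefined when the implant carries no flow and
    degenerate when the bleb sits at the reference pressure.
    """
    if state.q_i_ul_min <= 0:
        raise InfeasibleError("bleb resistance is undefined at zero implant flow")
    if state.p_b_mmhg <= p_r_mmhg:
        raise InfeasibleError(
            "degenerate bleb state: bleb pressure does not exceed the reference "
            f"pressure ({state.p_b_mmhg} <= {p_r_mmhg} mm Hg)"
        )
    return BlebModel((state.p_b_mmhg - p_r_mmhg) / state.q_i_ul_min)
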