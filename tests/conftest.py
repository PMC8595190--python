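import numpy as np
import pytest
from scipy.optimize import brentq

from sutureflow import EyeParameters, FluidProperties, ImplantGeometry, presets
from sutureflow.units import mmhg_to_pa, pa_to_mmhg


@pytest.fixture(scope="session")
def eye():
    return presets.baseline_eye()


@pytest.fixture(scope="session")
def fluid():
    return presets.aqueous_humor()


@pytest.fixture(scope="session")
def baerveldt():
    return presets.baerveldt_implant()


@pytest.fixture(scope="session")
def narrow():
    return presets.narrow_implant()


def open_tube_resistance_si(geometry: ImplantGeometry, fluid: FluidProperties) -> float:
    """R1 = 128 L mu / (pi D_i^4), Pa per m^3/s, no suture."""
    return (
        128.0
        * geometry.length_m
        * fluid.viscosity_pa_s
        / (np.pi * geometry.inner_diameter_m**4)
    )


def network_p_c2(
    eye: EyeParameters,
    geometry: ImplantGeometry,
    fluid: FluidProperties,
    p_c1_mmhg: float,
    resistance_ratio: float,
) -> float:
    """Independent oracle: solve the outflow resistor network explicitly.

    Never uses the package's closed-form correction formulas.  The anterior
    chamber drains through (a) the trabecular branch, linear with resistance
    (p_g - p_ev)/Q_0 and active only above p_ev, and (b) the tube + bleb in
    series.  The bleb resistance is calibrated from the first intervention
    (tube open, resistance R1), then the tube resistance is scaled by
    ``resistance_ratio`` and mass balance is re-solved for the new IOP.
    """
    r1 = open_tube_resistance_si(geometry, fluid)
    q0 = eye.q0_si
    pg, pev, pr = (
        mmhg_to_pa(eye.p_g_mmhg),
        mmhg_to_pa(eye.p_ev_mmhg),
        mmhg_to_pa(eye.p_r_mmhg),
    )
    p1 = mmhg_to_pa(p_c1_mmhg)
    r_tm = (pg - pev) / q0
    q_tm1 = (p1 - pev) / r_tm if p1 > pev else 0.0
    q_i1 = q0 - q_tm1
    assert q_i1 > 0, "first-intervention implant flow must be positive"
    p_b1 = p1 - r1 * q_i1
    assert p_b1 >= pr, "bleb pressure below reference: invalid oracle input"
    r_b = (p_b1 - pr) / q_i1
    r2 = resistance_ratio * r1

    def imbalance(p2: float) -> float:
        q_i2 = (p2 - pr) / (r2 + r_b)
        q_tm2 = (p2 - pev) / r_tm if p2 > pev else 0.0
        return q_i2 + q_tm2 - q0

    p2 = brentq(imbalance, pr, pg * 10, xtol=1e-12, rtol=8.9e-16)
    return pa_to_mmhg(p2)


def network_required_ratio(
    eye: EyeParameters,
    geometry: ImplantGeometry,
    fluid: FluidProperties,
    p_c1_mmhg: float,
    p_c2_mmhg: float,
) -> float:
    """Resistance ratio that makes the explicit network hit p_c2 (oracle)."""
    if p_c2_mmhg == p_c1_mmhg:
        return 1.0

    def f(ratio: float) -> float:
        return network_p_c2(eye, geometry, fluid, p_c1_mmhg, ratio) - p_c2_mmhg

    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        assert hi < 1e18
    return brentq(f, 1.0, hi, xtol=1e-15, rtol=8.9e-16)
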