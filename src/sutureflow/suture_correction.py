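"""Hypotony correction by intraluminal suture occlusion.

After a drainage implant is placed, the measured IOP ``p_c1`` may be too low
(hypotony).  Inserting a suture of diameter ``D_s`` into the tube raises the
tube's hydraulic resistance by the factor S2 * (1 - D_s/D_i)**-4 and hence
raises the IOP.  The bleb pressure is unknown in clinic; it is eliminated by
assuming the bleb morphology — hence its effective resistance R_b — does not
change between the two interventions.  With R_b eliminated, the change
p_c1 -> p_c2 depends only on measurable quantities and literature values.

Three regime cases arise from the IOPs relative to the episcleral venous
pressure ``p_ev`` (equality counts as trabecular-closed):

* both_closed — p_c1, p_c2 <= p_ev: the trabecular pathway carries no flow in
  either state; the IOP shift is simply the extra tube pressure drop at the
  full flow Q_0 and needs neither p_ev nor p_r.  This is the most frequent
  clinical case.
* mixed — p_c1 <= p_ev < p_c2: the suture reopens the trabecular pathway.
* both_open — p_ev < p_c1 <= p_c2: both states drain partly through the
  trabecular meshwork; a large-p_g approximation of this case drops the
  dependence on p_ev and p_r and coincides with the both_closed formula.

Forward problem: given D_s, predict p_c2.  Inverse problem: given a target
p_c2, find the required resistance ratio and invert it for D_s.  The inverse
D_s is an upper bound: bleb cicatrization between interventions or bending of
the suture inside the tube would add resistance beyond this model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InfeasibleError, SutureflowError
from .geometry import FluidProperties, ImplantGeometry, Placement, SutureConfig
from .shape_factor import (
    Resolution,
    invert_resistance_ratio,
    resistance_ratio,
    shape_factor,
)
from .steady_state import EyeParameters, Regime
from .units import mmhg_to_pa, pa_to_mmhg

_BOUNDARY_TOL_PA = 1e-9


class CaseLabel(str, Enum):
    BOTH_OPEN = "both_open"
    MIXED = "mixed"
    BOTH_CLOSED = "both_closed"


@dataclass(frozen=True)
class CorrectionProblem:
    """Inputs of one forward or inverse suture-correction calculation.

    Exactly one of ``d_s_um`` (forward: predict the IOP) and
    ``p_c2_target_mmhg`` (inverse: size the suture) should be set.
    """

    eye: EyeParameters
    geometry: ImplantGeometry
    p_c1_mmhg: float
    placement: Placement = Placement.WALL_TOUCHING
    d_s_um: Optional[float] = None
    p_c2_target_mmhg: Optional[float] = None
    use_large_pg_approximation: bool = False
    fluid: FluidProperties = FluidProperties()
    resolution: Resolution = Resolution()

    def __post_init__(self):
        if not (self.eye.p_r_mmhg <= self.p_c1_mmhg < self.eye.p_g_mmhg):
            raise InfeasibleError(
                f"measured IOP p_c1={self.p_c1_mmhg} mm Hg must lie in "
                f"[p_r, p_g) = [{self.eye.p_r_mmhg}, {self.eye.p_g_mmhg})"
            )
        if self.d_s_um is not None and not (
            0 <= self.d_s_um < self.geometry.inner_diameter_um
        ):
            raise InfeasibleError("suture diameter must satisfy 0 <= D_s < D_i")


@dataclass(frozen=True)
class CorrectionSolution:
    """Output of the forward/inverse suture solvers.

    ``d_s_um`` from the inverse solver is an upper bound on the suture
    diameter actually needed (``upper_bound_note``): the model assumes the
    minimum-resistance configuration — straight suture, unchanged bleb.
    """

    resistance_ratio_required: float
    shape_factor_2: float
    kappa: float
    d_s_um: float
    p_c2_mmhg: float
    regime_before: Regime
    regime_after: Regime
    case_label: CaseLabel
    upper_bound_note: bool = False
    at_case_boundary: bool = False


def _inv_conductance_pa(problem: CorrectionProblem) -> float:
    """A = pi * D_i^4 / (128 L_v mu Q_0), in 1/Pa."""
    di = problem.geometry.inner_diameter_m
    lv = problem.geometry.length_m
    mu = problem.fluid.viscosity_pa_s
    q0 = problem.eye.q0_si
    return np.pi * di**4 / (128.0 * lv * mu * q0)


def classify_case(p_c1_mmhg: float, p_c2_mmhg: float, p_ev_mmhg: float) -> CaseLabel:
    """Regime case from the two IOPs; equality with p_ev counts as closed."""
    if p_c1_mmhg <= p_ev_mmhg:
        return CaseLabel.BOTH_CLOSED if p_c2_mmhg <= p_ev_mmhg else CaseLabel.MIXED
    return CaseLabel.BOTH_OPEN


def required_resistance_ratio(problem: CorrectionProblem) -> float:
    """Resistance ratio S2 * (1 - kappa)**-4 needed to reach the target IOP.

    Evaluates the case-appropriate elimination of the bleb pressure; equals
    exactly 1 at p_c2 = p_c1 and grows monotonically with the target.  With
    ``use_large_pg_approximation`` the both_open case drops its dependence
    on p_ev and p_r (valid when p_g dominates both IOPs; this is also the
    formula obtained when the implant-bleb branch carries nearly all flow).
    """
    if problem.p_c2_target_mmhg is None:
        raise ValueError("required_resistance_ratio needs p_c2_target_mmhg")
    p2m = problem.p_c2_target_mmhg
    p1m = problem.p_c1_mmhg
    eye = problem.eye
    if p2m < p1m:
        raise InfeasibleError(
            f"target IOP {p2m} mm Hg is below the measured IOP {p1m} mm Hg: "
            "a suture cannot lower the IOP"
        )
    if p2m >= eye.p_g_mmhg:
        raise InfeasibleError(
            f"target IOP {p2m} mm Hg must lie below the pre-surgery IOP "
            f"{eye.p_g_mmhg} mm Hg"
        )
    a = _inv_conductance_pa(problem)
    p1, p2 = mmhg_to_pa(p1m), mmhg_to_pa(p2m)
    pg, pev, pr = (
        mmhg_to_pa(eye.p_g_mmhg),
        mmhg_to_pa(eye.p_ev_mmhg),
        mmhg_to_pa(eye.p_r_mmhg),
    )
    case = classify_case(p1m, p2m, eye.p_ev_mmhg)
    if case == CaseLabel.BOTH_CLOSED:
        return 1.0 + a * (p2 - p1)
    if case == CaseLabel.MIXED:
        return 1.0 + a * ((p2 * (pg - pev - pr) + pev * pr) / (pg - p2) - p1)
    if problem.use_large_pg_approximation:
        return 1.0 + a * (p2 - p1)
    return 1.0 + a * (p2 - p1) * (pg - pr) * (pg - pev) / ((pg - p1) * (pg - p2))


def suture_diameter_for_target(problem: CorrectionProblem) -> CorrectionSolution:
    """Suture diameter achieving the target IOP (inverse problem).

    Composes the required resistance ratio with the monotone inversion of
    kappa -> S(kappa) * (1 - kappa)**-4 for the requested placement.  The
    returned diameter is an upper bound (see module docstring).
    """
    ratio = required_resistance_ratio(problem)
    kappa = invert_resistance_ratio(ratio, problem.placement)
    d_s = kappa * problem.geometry.inner_diameter_um
    s2 = shape_factor(kappa, problem.placement, problem.resolution)
    eye = problem.eye
    p2m = problem.p_c2_target_mmhg
    case = classify_case(problem.p_c1_mmhg, p2m, eye.p_ev_mmhg)
    return CorrectionSolution(
        resistance_ratio_required=ratio,
        shape_factor_2=s2,
        kappa=kappa,
        d_s_um=d_s,
        p_c2_mmhg=p2m,
        regime_before=(
            Regime.TRABECULAR_CLOSED
            if problem.p_c1_mmhg <= eye.p_ev_mmhg
            else Regime.TRABECULAR_OPEN
        ),
        regime_after=(
            Regime.TRABECULAR_CLOSED
            if p2m <= eye.p_ev_mmhg
            else Regime.TRABECULAR_OPEN
        ),
        case_label=case,
        upper_bound_note=True,
    )


def predicted_iop_after_suture(problem: CorrectionProblem) -> CorrectionSolution:
    """IOP after inserting a given suture (forward problem).

    With p_c1 above p_ev the both_open formula applies directly (the IOP can
    only rise, so the trabecular pathway stays open).  With p_c1 at or below
    p_ev the both_closed formula is tried first; if its result crosses p_ev
    the closed assumption is inconsistent and the mixed formula is used.
    Exactly one case can be self-consistent (the network response is
    monotone); the implementation verifies this and flags exact-boundary
    states instead of failing.
    """
    if problem.d_s_um is None:
        raise ValueError("predicted_iop_after_suture needs d_s_um")
    eye = problem.eye
    geo = problem.geometry
    kappa = problem.d_s_um / geo.inner_diameter_um
    s2 = (
        1.0
        if kappa == 0.0
        else shape_factor(kappa, problem.placement, problem.resolution)
    )
    di4 = geo.inner_diameter_m**4
    dh4 = (geo.inner_diameter_m * (1.0 - kappa)) ** 4
    lv = geo.length_m
    mu = problem.fluid.viscosity_pa_s
    q0 = eye.q0_si
    b = 128.0 * lv * mu * q0  # Pa m^4 scale of the tube branch
    excess = di4 * s2 - dh4  # > 0 whenever a suture is present
    p1 = mmhg_to_pa(problem.p_c1_mmhg)
    pg, pev, pr = (
        mmhg_to_pa(eye.p_g_mmhg),
        mmhg_to_pa(eye.p_ev_mmhg),
        mmhg_to_pa(eye.p_r_mmhg),
    )

    boundary = False
    if problem.p_c1_mmhg > eye.p_ev_mmhg:
        case = CaseLabel.BOTH_OPEN
        num = np.pi * di4 * dh4 * p1 * (pg - pev) * (pg - pr) - b * pg * (
            pg - p1
        ) * (dh4 - di4 * s2)
        den = np.pi * di4 * dh4 * (pg - pev) * (pg - pr) - b * (pg - p1) * (
            dh4 - di4 * s2
        )
        p2 = num / den
    else:
        # both_closed attempt: extra tube drop at the full flow Q_0
        p2 = p1 + b * excess / (np.pi * di4 * dh4)
        if p2 <= pev:
            case = CaseLabel.BOTH_CLOSED
        else:
            case = CaseLabel.MIXED
            num = np.pi * di4 * dh4 * (pev * pr - p1 * pg) + b * pg * (
                dh4 - di4 * s2
            )
            den = np.pi * di4 * dh4 * (pev + pr - p1 - pg) + b * (dh4 - di4 * s2)
            p2 = num / den
            if p2 < pev - _BOUNDARY_TOL_PA:
                raise SutureflowError(
                    "no self-consistent regime case: both the both_closed and "
                    "mixed balances place the corrected IOP on the wrong side "
                    "of p_ev"
                )
            if p2 <= pev:
                p2, boundary = pev, True

    p2m = pa_to_mmhg(p2)
    return CorrectionSolution(
        resistance_ratio_required=(
            s2 / (1.0 - kappa) ** 4 if kappa > 0 else 1.0
        ),
        shape_factor_2=s2,
        kappa=kappa,
        d_s_um=problem.d_s_um,
        p_c2_mmhg=p2m,
        regime_before=(
            Regime.TRABECULAR_CLOSED
            if problem.p_c1_mmhg <= eye.p_ev_mmhg
            else Regime.TRABECULAR_OPEN
        ),
        regime_after=(
            Regime.TRABECULAR_CLOSED if p2m <= eye.p_ev_mmhg else Regime.TRABECULAR_OPEN
        ),
        case_label=case,
        upper_bound_note=False,
        at_case_boundary=boundary,
    )


def iop_increase_sweep(
    eye: EyeParameters,
    geometry: ImplantGeometry,
    placement: Union[Placement, str],
    p_c1_grid: Sequence[float],
    d_s_grid: Sequence[float],
    fluid: FluidProperties = FluidProperties(),
    resolution: Resolution = Resolution(),
) -> pd.DataFrame:
    """Forward predictions over a (p_c1, D_s) grid.

    Returns a tidy table with columns ``p_c1_mmHg, D_s_um, p_c2_mmHg, case``;
    infeasible cells are kept with ``case='error'`` and NaN pressure so a
    sweep never aborts wholesale.  Below the mixed-case window the increase
    p_c2 - p_c1 is independent of p_c1; above p_ev it decreases with p_c1
    (a higher p_c1 means a stiffer bleb, so the implant carries less flow and
    the suture matters less).
    """
    placement = Placement(placement)
    rows = []
    for p1 in p_c1_grid:
        for ds in d_s_grid:
            try:
                prob = CorrectionProblem(
                    eye=eye,
                    geometry=geometry,
                    p_c1_mmhg=float(p1),
                    placement=placement,
                    d_s_um=float(ds),
                    fluid=fluid,
                    resolution=resolution,
                )
                sol = predicted_iop_after_suture(prob)
                rows.append((p1, ds, sol.p_c2_mmhg, sol.case_label.value))
            except SutureflowError:
                rows.append((p1, ds, np.nan, "error"))
    return pd.DataFrame(rows, columns=["p_c1_mmHg", "D_s_um", "p_c2_mmHg", "case"])
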