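"""Cross-section shape factor of the implant lumen.

The pressure drop of fully developed Stokes flow through a straight duct of
arbitrary cross-section obeys a generalized Hagen–Poiseuille law

    dp = 128 * S * L * mu * Q / (pi * D_h**4),

where ``D_h`` is the hydraulic diameter and ``S`` is a dimensionless shape
factor that equals 1 for a circular bore.  ``S`` is obtained from the
unit-forced Poisson problem for the scaled axial velocity v on the section
scaled so that D_h = 1:

    S = (pi / 128) * (integral of v over the section) ** -1.

For a tube of bore D_i carrying a cylindrical suture of diameter D_s the
hydraulic diameter is D_h = D_i - D_s.  A coaxial (concentric) suture admits
the closed-form annulus solution; a suture resting on the tube wall
(internally tangent circles) requires the numerical solve.  The wall-touching
section always has the smaller S, i.e. the smaller hydraulic resistance at
equal suture diameter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import _poisson
from .errors import GeometryError, InfeasibleError, NumericalAccuracyError
from .geometry import CrossSection, Placement

__all__ = [
    "Resolution",
    "ShapeFactorResult",
    "concentric_shape_factor",
    "poisson_shape_factor",
    "shape_factor",
    "tabulate_shape_factor",
    "resistance_ratio",
    "invert_resistance_ratio",
    "curve_to_csv",
    "curve_from_csv",
]

#: Default relative accuracy demanded of the numerical shape factor.
DEFAULT_RTOL = 5e-3

#: Root-finding bracket offset: kappa is searched on [0, 1 - BRACKET_DELTA].
BRACKET_DELTA = 1e-6


@dataclass(frozen=True)
class Resolution:
    """Discretization control for the Poisson solve.

    ``cells_per_gap`` sets the base grid so that the annular gap width
    (D_i - D_s)/2 is spanned by at least that many cells; the solver then
    refines (doubling) until the two-level Richardson error estimate falls
    below ``rtol`` or the grid exceeds ``max_cells`` across the section.
    """

    cells_per_gap: int = 24
    min_cells: int = 96
    max_cells: int = 3072
    rtol: float = DEFAULT_RTOL

    def base_cells(self, kappa: float) -> int:
        gap_fraction = (1.0 - kappa) / 2.0
        n = int(np.ceil(self.cells_per_gap / max(gap_fraction, 1e-12)))
        return int(np.clip(n, self.min_cells, self.max_cells))


@dataclass(frozen=True)
class ShapeFactorResult:
    """A shape-factor value with its numerical provenance."""

    value: float
    method: str  # "closed_form" | "poisson_numeric"
    resolution: dict = field(default_factory=dict)
    error_estimate: float = 0.0
    velocity_field: Optional[dict] = field(default=None, compare=False, repr=False)


def concentric_shape_factor(kappa: float) -> float:
    """Closed-form shape factor of a concentric circular annulus.

    Parameters
    ----------
    kappa : float
        Diameter ratio D_s / D_i in [0, 1).  kappa = 0 is the open tube
        (S = 1, taken as the analytic limit: the log term's prefactor
        vanishes faster than the log diverges).
    """
    if not (0.0 <= kappa < 1.0):
        raise GeometryError(f"kappa must lie in [0, 1), got {kappa}")
    if kappa == 0.0:
        return 1.0
    eps = 1.0 - kappa
    if eps < 0.1:
        # the printed form cancels catastrophically as the gap closes
        # (terms O(eps) conspire to a residual O(eps^3)); switch to its
        # series in the gap width, accurate to ~3e-9 relative at eps = 0.1
        brace = eps**3 * (
            4.0 / 3.0
            + eps * (-2.0 / 3.0
            + eps * (1.0 / 45.0
            + eps * (1.0 / 90.0
            + eps * (8.0 / 945.0
            + eps * (1.0 / 140.0
            + eps * (353.0 / 56700.0
            + eps * (25.0 / 4536.0
            + eps * (2306.0 / 467775.0))))))))
        )
    else:
        brace = 1.0 - kappa**4 + (1.0 - kappa**2) ** 2 / np.log(kappa)
    return eps**4 / brace


def _section_domain(section: CrossSection, tangency_gap: float):
    """Scaled solver domain plus the fourth power of the scaled D_h."""
    if section.placement == Placement.CUSTOM:
        dom = _poisson.PolygonDomain(section.custom_boundary)
        # conventional hydraulic diameter 4A/P for an arbitrary section
        x0, y0, x1, y1 = dom.bounds
        ext = max(x1 - x0, y1 - y0)
        dh_scaled = 4.0 * dom.area / dom.perimeter / ext
        b = section.custom_boundary
        scaled = (b - [x0, y0]) / ext
        dom = _poisson.PolygonDomain(scaled)
        return dom, dh_scaled**4, 0.0
    kappa = section.kappa
    wall = section.placement == Placement.WALL_TOUCHING
    dom = _poisson.annulus_domain(kappa, wall, gap=tangency_gap)
    # solved at outer diameter 1, so scaled D_h = 1 - kappa
    return dom, (1.0 - kappa) ** 4, kappa


def poisson_shape_factor(
    section: CrossSection,
    resolution: Resolution = Resolution(),
    tangency_gap: float = 0.0,
    return_field: bool = False,
) -> ShapeFactorResult:
    """Shape factor of an arbitrary cross-section by the Poisson solve.

    Solves -laplace(v) = 1, v = 0 on the contour, on the section scaled to
    O(1) size; the result is rescaled to the D_h = 1 normalization, so
    S = (pi/128) * D_h_scaled**4 / integral(v).  Two successive grids
    (h, h/2) give a Richardson error estimate and the reported value is the
    Richardson-extrapolated one.  The grid is refined until the estimate
    meets ``resolution.rtol``; failure to converge within
    ``resolution.max_cells`` raises :class:`NumericalAccuracyError`.

    ``tangency_gap`` (fraction of D_i) pulls a wall-touching suture off the
    wall; it exists for sensitivity studies only and defaults to exact
    tangency.
    """
    dom, dh4, kappa = _section_domain(section, tangency_gap)
    n = resolution.base_cells(kappa)
    integ_coarse, _ = _poisson.solve_poisson(dom, n, order=2)
    while True:
        n_fine = 2 * n
        integ_fine, fld = _poisson.solve_poisson(
            dom, n_fine, order=2, return_field=return_field
        )
        s_coarse = (np.pi / 128.0) * dh4 / integ_coarse
        s_fine = (np.pi / 128.0) * dh4 / integ_fine
        s_ext = (4.0 * s_fine - s_coarse) / 3.0  # O(h^2) Richardson
        err = abs(s_fine - s_coarse) / (3.0 * abs(s_ext))
        if err <= resolution.rtol:
            break
        if n_fine >= resolution.max_cells:
            raise NumericalAccuracyError(
                f"shape-factor solve did not reach rtol={resolution.rtol:g} "
                f"at max grid {n_fine} (error estimate {err:.2e})"
            )
        n, integ_coarse = n_fine, integ_fine
    return ShapeFactorResult(
        value=float(s_ext),
        method="poisson_numeric",
        resolution={"cells": n_fine, "cells_coarse": n, "scheme": "shortley_weller"},
        error_estimate=float(err),
        velocity_field=fld,
    )


def shape_factor(
    kappa: float,
    placement: Union[Placement, str],
    resolution: Resolution = Resolution(),
    exact: bool = False,
) -> float:
    """S(kappa) for either suture placement.

    Concentric sutures use the closed form.  Wall-touching sutures use the
    cached monotone interpolation table by default (one-off Poisson solves at
    the table knots, then cheap evaluation everywhere — in particular inside
    root-finding loops and parameter sweeps); ``exact=True`` forces a fresh
    Poisson solve at this kappa and ``resolution``.
    """
    placement = Placement(placement)
    if placement == Placement.CONCENTRIC:
        return concentric_shape_factor(kappa)
    if placement == Placement.WALL_TOUCHING:
        if not (0.0 <= kappa < 1.0):
            raise GeometryError(f"kappa must lie in [0, 1), got {kappa}")
        if kappa == 0.0:
            return 1.0
        if exact:
            return _wall_touching_cached(round(float(kappa), 12), resolution)
        return float(_wall_touching_S_interp(kappa))
    raise GeometryError("custom sections require poisson_shape_factor directly")


@lru_cache(maxsize=256)
def _wall_touching_cached(kappa: float, resolution: Resolution) -> float:
    section = CrossSection(1.0, kappa, Placement.WALL_TOUCHING)
    return poisson_shape_factor(section, resolution).value


# --------------------------------------------------------------------------
# tabulation and interpolation

#: Default kappa knots of the wall-touching interpolation table: 33 values,
#: anchored at the exact endpoints S(0) = 1 and S(1) = 0.
DEFAULT_TABLE_KNOTS = tuple(
    np.concatenate([np.linspace(0.0, 0.93, 32), [1.0]]).tolist()
)

#: Lighter discretization for the 31 interior table solves; the interpolation
#: error dominates the table anyway.
TABLE_RESOLUTION = Resolution(cells_per_gap=12, min_cells=96, max_cells=3072, rtol=5e-3)


def tabulate_shape_factor(
    placement: Union[Placement, str],
    kappa_grid: Sequence[float],
    resolution: Resolution = Resolution(),
    exact: bool = False,
) -> np.ndarray:
    """Evaluate S on a strictly increasing kappa grid.

    Returns an (N, 2) array of (kappa, S) pairs, monotone decreasing in S,
    suitable for interpolation or CSV export.  Per-point failures propagate
    with the offending kappa named.
    """
    placement = Placement(placement)
    grid = np.asarray(list(kappa_grid), dtype=float)
    if grid.size == 0:
        return np.empty((0, 2))
    if np.any((grid < 0) | (grid >= 1)):
        raise GeometryError("all kappa values must lie in [0, 1)")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise GeometryError("kappa grid must be strictly increasing")
    out = np.empty((grid.size, 2))
    failures = []
    for i, k in enumerate(grid):
        out[i, 0] = k
        try:
            out[i, 1] = shape_factor(float(k), placement, resolution, exact=exact)
        except NumericalAccuracyError as exc:  # pragma: no cover - rare path
            failures.append((float(k), str(exc)))
            out[i, 1] = np.nan
    if failures:
        raise NumericalAccuracyError(
            "shape-factor tabulation failed at kappa = "
            + ", ".join(f"{k:g} ({msg})" for k, msg in failures)
        )
    return out


@lru_cache(maxsize=8)
def _wall_touching_interpolator(
    knots: tuple = DEFAULT_TABLE_KNOTS, resolution: Resolution = TABLE_RESOLUTION
) -> PchipInterpolator:
    """Monotone PCHIP interpolant of the wall-touching S(kappa) curve.

    Built lazily from Poisson solves at the interior knots, anchored at the
    exact limits S(0) = 1 and S(1) = 0; monotonicity of the data is preserved
    by the PCHIP construction, which keeps root finding on the resistance
    ratio well posed without a PDE solve per iteration.
    """
    ks = np.asarray(knots)
    vals = np.empty_like(ks)
    vals[0], vals[-1] = 1.0, 0.0
    for i, k in enumerate(ks[1:-1], start=1):
        vals[i] = _wall_touching_cached(round(float(k), 12), resolution)
    return PchipInterpolator(ks, vals, extrapolate=False)


def _wall_touching_S_interp(kappa) -> np.ndarray:
    interp = _wall_touching_interpolator()
    # clip away rounding-level negatives next to the S(1) = 0 anchor so the
    # resistance ratio stays positive and monotone up to the bracket end
    return np.clip(np.asarray(interp(np.clip(kappa, 0.0, 1.0))), 1e-12, 1.0)


# --------------------------------------------------------------------------
# resistance ratio and its inverse

def resistance_ratio(
    kappa: float,
    placement: Union[Placement, str] = Placement.CONCENTRIC,
    exact: bool = False,
    resolution: Resolution = Resolution(),
) -> float:
    """Hydraulic-resistance ratio of the sutured tube to the open tube.

    The occluded tube's resistance exceeds the open one's by the factor
    S(kappa) * (1 - kappa)**-4; this is the quantity a suture-design
    calculation must match.  Equals 1 at kappa = 0 and increases without
    bound as the suture fills the bore.

    For wall-touching placement the default path evaluates the cached
    monotone interpolation table; ``exact=True`` forces a fresh Poisson
    solve at this kappa.
    """
    placement = Placement(placement)
    if not (0.0 <= kappa < 1.0):
        raise GeometryError(f"kappa must lie in [0, 1), got {kappa}")
    if kappa == 0.0:
        return 1.0
    if placement == Placement.CONCENTRIC:
        s = concentric_shape_factor(kappa)
    elif exact:
        s = shape_factor(kappa, placement, resolution)
    else:
        s = float(_wall_touching_S_interp(kappa))
    return s / (1.0 - kappa) ** 4


def invert_resistance_ratio(
    target_ratio: float,
    placement: Union[Placement, str] = Placement.CONCENTRIC,
) -> float:
    """The kappa whose resistance ratio equals ``target_ratio``.

    Exploits strict monotonicity of the ratio for bracketed root finding on
    [0, 1 - 1e-6].  ``target_ratio < 1`` is infeasible (a suture can only
    raise resistance); a ratio beyond the value at the bracket end is
    reported as "suture alone insufficient" with the attainable bound.
    """
    placement = Placement(placement)
    if target_ratio < 1.0:
        raise InfeasibleError(
            f"resistance ratio {target_ratio:g} < 1: a suture cannot lower the "
            "tube resistance (is the requested IOP below the current one?)"
        )
    if target_ratio == 1.0:
        return 0.0

    def f(k: float) -> float:
        return resistance_ratio(k, placement) - target_ratio

    k_hi = 1.0 - BRACKET_DELTA
    f_hi = f(k_hi)
    if f_hi < 0:
        raise InfeasibleError(
            "suture alone insufficient: required resistance ratio "
            f"{target_ratio:.4g} exceeds the attainable bound "
            f"{target_ratio + f_hi:.4g} at kappa = {k_hi}"
        )
    return float(brentq(f, 0.0, k_hi, xtol=1e-14, rtol=8.9e-16))


# --------------------------------------------------------------------------
# CSV interchange

def curve_to_csv(curve: np.ndarray, path_or_buf) -> None:
    """Write an (N, 2) (kappa, S) table as ``kappa,shape_factor`` CSV."""
    header = "kappa,shape_factor"
    np.savetxt(path_or_buf, np.asarray(curve), delimiter=",", header=header,
               comments="", fmt="%.12g")


def curve_from_csv(path_or_buf) -> np.ndarray:
    """Read a ``kappa,shape_factor`` CSV back into an (N, 2) array."""
    return np.loadtxt(path_or_buf, delimiter=",", skiprows=1, ndmin=2)
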