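"""Geometry and fluid-property types.

The drainage implant is modelled as a straight cylindrical tube of inner
diameter ``D_i`` and length ``L_v``.  An intraluminal suture of diameter
``D_s`` turns the lumen into an annulus (concentric or internally tangent,
"wall-touching"); the hydraulic diameter of the annulus is ``D_h = D_i − D_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError


class Placement(str, Enum):
    """Position of the suture inside the tube lumen."""

    CONCENTRIC = "concentric"
    WALL_TOUCHING = "wall_touching"
    CUSTOM = "custom"


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid, characterized by its dynamic viscosity.

    Parameters
    ----------
    viscosity_mpa_s : float
        Dynamic viscosity in mPa·s.  Aqueous humor is ~0.75 mPa·s.
    """

    viscosity_mpa_s: float = 0.75

    def __post_init__(self):
        if self.viscosity_mpa_s <= 0:
            raise ValueError("viscosity must be > 0")

    @property
    def viscosity_pa_s(self) -> float:
        return self.viscosity_mpa_s * 1e-3


@dataclass(frozen=True)
class ImplantGeometry:
    """Drainage-tube bore: inner diameter D_i (µm) and length L_v (mm)."""

    inner_diameter_um: float
    length_mm: float

    def __post_init__(self):
        if self.inner_diameter_um <= 0:
            raise GeometryError("inner diameter must be > 0")
        if self.length_mm <= 0:
            raise GeometryError("implant length must be > 0")

    @property
    def inner_diameter_m(self) -> float:
        return self.inner_diameter_um * 1e-6

    @property
    def length_m(self) -> float:
        return self.length_mm * 1e-3


@dataclass(frozen=True)
class SutureConfig:
    """Intraluminal suture: diameter D_s (µm) and placement in the lumen."""

    diameter_um: float
    placement: Placement = Placement.WALL_TOUCHING

    def __post_init__(self):
        if self.diameter_um < 0:
            raise GeometryError("suture diameter must be >= 0")
        if self.placement == Placement.CUSTOM:
            raise GeometryError("a suture placement must be concentric or wall_touching")


@dataclass(frozen=True)
class CrossSection:
    """Planar cross-section of the implant lumen.

    ``suture_diameter_um = 0`` means an open circular tube.  For
    ``placement = CUSTOM`` the flow domain is described by
    ``custom_boundary``: a closed polyline, an (N, 2) array of planar
    coordinates (any consistent length unit; the shape factor is scale
    invariant).
    """

    outer_diameter_um: float
    suture_diameter_um: float = 0.0
    placement: Placement = Placement.CONCENTRIC
    custom_boundary: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self):
        if self.placement != Placement.CUSTOM:
            if self.outer_diameter_um <= 0:
                raise GeometryError("outer diameter must be > 0")
            if not (0 <= self.suture_diameter_um < self.outer_diameter_um):
                raise GeometryError(
                    "suture diameter must satisfy 0 <= D_s < D_i "
                    f"(got D_s={self.suture_diameter_um}, D_i={self.outer_diameter_um})"
                )
        else:
            if self.custom_boundary is None:
                raise GeometryError("custom placement requires custom_boundary")
            b = np.asarray(self.custom_boundary, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
                raise GeometryError("custom_boundary must be an (N>=3, 2) polyline")
            object.__setattr__(self, "custom_boundary", b)

    @property
    def kappa(self) -> float:
        """Diameter ratio κ = D_s / D_i."""
        if self.placement == Placement.CUSTOM:
            raise GeometryError("kappa is undefined for a custom cross-section")
        return self.suture_diameter_um / self.outer_diameter_um

    def hydraulic_diameter_um(self) -> float:
        """D_h = D_i − D_s, the length scale of the Poiseuille law."""
        if self.placement == Placement.CUSTOM:
            raise GeometryError(
                "hydraulic diameter of a custom section is not defined here; "
                "supply it explicitly"
            )
        dh = self.outer_diameter_um - self.suture_diameter_um
        if dh <= 0:
            raise GeometryError("hydraulic diameter must be > 0")
        return dh

    @classmethod
    def from_implant(
        cls, geometry: ImplantGeometry, suture: Optional[SutureConfig] = None
    ) -> "CrossSection":
        if suture is None or suture.diameter_um == 0:
            return cls(geometry.inner_diameter_um, 0.0, Placement.CONCENTRIC)
        if suture.diameter_um >= geometry.inner_diameter_um:
            raise GeometryError("suture diameter must be smaller than the tube bore")
        return cls(geometry.inner_diameter_um, suture.diameter_um, suture.placement)


def polyline_from_csv(path) -> np.ndarray:
    """Load a closed polyline from a two-column CSV of planar coordinates."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[1] != 2:
        raise GeometryError("polyline CSV must have exactly two columns")
    return arr
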