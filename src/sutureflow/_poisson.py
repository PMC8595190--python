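"""Finite-difference Poisson solver for duct cross-sections.

Solves the unit-forced Dirichlet problem

    -laplace(v) = 1  in the cross-section,   v = 0 on its boundary,

whose solution is the scaled fully-developed axial velocity profile of
Stokes flow in a straight duct.  Two discretizations are provided:

* ``order=2`` — a second-order scheme with Shortley–Weller treatment of the
  curved boundary: at grid points adjacent to the boundary the stencil arms
  are shortened to the exact intersection of the grid line with the contour,
  preserving O(h^2) accuracy on irregular domains.  This is the production
  path.
* ``order=1`` — a plain 5-point Laplacian on the mask of interior points,
  with every exterior neighbour treated as a homogeneous boundary value at
  distance h.  First-order at the boundary; kept as a deliberately simple
  independent cross-check.

Grids are Cartesian with cell-centred nodes, so no node ever falls exactly
on the boundary contour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError

_TMIN = 1e-9  # floor on boundary-arm length, in units of h


@dataclass(frozen=True)
class CircleSpec:
    """One circular boundary: keep the flow inside (outer wall) or outside
    (an obstacle such as a suture)."""

    cx: float
    cy: float
    r: float
    keep_inside: bool


class AnnulusDomain:
    """Flow domain bounded by circles: one outer wall, optional obstacles.

    All coordinates are in solver units; callers are expected to scale the
    physical section so its bounding box is O(1).
    """

    def __init__(self, circles: list[CircleSpec]):
        outers = [c for c in circles if c.keep_inside]
        if len(outers) != 1:
            raise GeometryError("exactly one outer circle is required")
        self.circles = circles
        o = outers[0]
        self.bounds = (o.cx - o.r, o.cy - o.r, o.cx + o.r, o.cy + o.r)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        inside = np.ones(np.broadcast(x, y).shape, dtype=bool)
        for c in self.circles:
            d2 = (x - c.cx) ** 2 + (y - c.cy) ** 2
            if c.keep_inside:
                inside &= d2 < c.r**2
            else:
                inside &= d2 > c.r**2
        return inside

    def ray_distance(
        self, x: np.ndarray, y: np.ndarray, ex: float, ey: float, h: float
    ) -> np.ndarray:
        """Distance along (ex, ey) from interior points (x, y) to the nearest
        boundary crossing, for points whose neighbour at distance h is outside.
        """
        t = np.full(x.shape, np.inf)
        for c in self.circles:
            px, py = x - c.cx, y - c.cy
            b = ex * px + ey * py
            c0 = px**2 + py**2 - c.r**2
            disc = b**2 - c0
            if c.keep_inside:
                # c0 < 0 inside: one positive root
                tc = -b + np.sqrt(np.maximum(disc, 0.0))
                t = np.minimum(t, tc)
            else:
                ok = (disc >= 0) & (b < 0)
                sq = np.sqrt(np.maximum(disc, 0.0))
                tc = np.where(ok, -b - sq, np.inf)
                tc = np.where(tc > 0, tc, np.inf)
                t = np.minimum(t, tc)
        return np.clip(t, _TMIN * h, h)


class PolygonDomain:
    """Flow domain bounded by a closed polyline (shapely-backed)."""

    def __init__(self, boundary: np.ndarray):
        from shapely.geometry import Polygon

        poly = Polygon(boundary)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("custom boundary does not enclose a valid region")
        self.polygon = poly
        self._ring = poly.exterior
        self.bounds = poly.bounds

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        return self.polygon.length

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        from shapely import contains_xy

        return contains_xy(self.polygon, x, y)

    def ray_distance(
        self, x: np.ndarray, y: np.ndarray, ex: float, ey: float, h: float
    ) -> np.ndarray:
        from shapely.geometry import LineString, Point

        out = np.empty(x.shape)
        for i, (xi, yi) in enumerate(zip(np.ravel(x), np.ravel(y))):
            seg = LineString([(xi, yi), (xi + 1.5 * h * ex, yi + 1.5 * h * ey)])
            hit = seg.intersection(self._ring)
            if hit.is_empty:
                out.flat[i] = h
            else:
                out.flat[i] = hit.distance(Point(xi, yi))
        return np.clip(out, _TMIN * h, h)


def solve_poisson(
    domain, n: int, order: int = 2, return_field: bool = False
) -> Tuple[float, Optional[dict]]:
    """Solve -laplace(v) = 1 with v = 0 on the boundary of ``domain``.

    Parameters
    ----------
    domain
        Object exposing ``bounds``, ``contains`` and ``ray_distance``.
    n
        Number of grid cells across the longest side of the bounding box.
    order
        2 for Shortley–Weller (production), 1 for the masked 5-point oracle.
    return_field
        If true, also return the grid and solution for diagnostics.

    Returns
    -------
    integral : float
        The integral of v over the domain (midpoint quadrature).
    field : dict or None
        ``{"x", "y", "v"}`` arrays when requested.
    """
    x0, y0, x1, y1 = domain.bounds
    ext = max(x1 - x0, y1 - y0)
    h = ext / n
    nx = int(np.ceil((x1 - x0) / h))
    ny = int(np.ceil((y1 - y0) / h))
    xs = x0 + (np.arange(nx) + 0.5) * h
    ys = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = domain.contains(X, Y)
    m = int(inside.sum())
    if m < 8:
        raise GeometryError("flow region is below the resolvable scale at this grid")

    idx = -np.ones((nx, ny), dtype=np.int64)
    idx[inside] = np.arange(m)
    px, py = X[inside], Y[inside]

    # arm lengths toward the 4 neighbours; shortened where the boundary cuts in
    pad = -np.ones((nx + 2, ny + 2), dtype=np.int64)
    pad[1:-1, 1:-1] = idx
    dirs = {
        "E": (1, 0), "W": (-1, 0), "N": (0, 1), "S": (0, -1),
    }
    arm = {}
    nbr = {}
    for name, (dx, dy) in dirs.items():
        nb = pad[1 + dx : 1 + dx + nx, 1 + dy : 1 + dy + ny][inside]
        nbr[name] = nb
        t = np.full(m, h)
        cut = nb < 0
        if order == 2 and cut.any():
            t[cut] = domain.ray_distance(px[cut], py[cut], float(dx), float(dy), h)
        arm[name] = t

    hE, hW, hN, hS = arm["E"], arm["W"], arm["N"], arm["S"]
    diag = 2.0 / (hE * hW) + 2.0 / (hN * hS)
    rows = [np.arange(m)]
    cols = [np.arange(m)]
    vals = [diag]
    for name, hp, hm in (("E", hE, hW), ("W", hW, hE), ("N", hN, hS), ("S", hS, hN)):
        nb = nbr[name]
        link = nb >= 0
        rows.append(np.arange(m)[link])
        cols.append(nb[link])
        vals.append(-2.0 / (hp[link] * (hp[link] + hm[link])))
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    v = spla.spsolve(A, np.ones(m))
    integral = float(v.sum()) * h * h
    field = None
    if return_field:
        V = np.full((nx, ny), np.nan)
        V[inside] = v
        field = {"x": xs, "y": ys, "v": V}
    return integral, field


def annulus_domain(kappa: float, wall_touching: bool, gap: float = 0.0) -> AnnulusDomain:
    """Tube-with-suture cross-section scaled to outer diameter 1.

    ``gap`` (same units, i.e. fraction of D_i) optionally pulls a
    wall-touching suture off the wall for sensitivity studies.
    """
    circles = [CircleSpec(0.0, 0.0, 0.5, True)]
    if kappa > 0:
        if wall_touching:
            cx = (1.0 - kappa) / 2.0 - gap
        else:
            cx = 0.0
        circles.append(CircleSpec(cx, 0.0, kappa / 2.0, False))
    return AnnulusDomain(circles)
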