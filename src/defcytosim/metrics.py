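"""Shape and stress metrics for deformability cytometry.

The deformation index (DI) is the long/short axis ratio of the deformed
cell, DI = 1 for an undeformed circle.  "Axes" are taken from the
inertia-equivalent ellipse of the contour (the ellipse with the same area
and second area moments), which is rotation-invariant and robust for the
triangle-like shapes cells adopt in the channel; an axis-aligned
minimum-rotated-rectangle variant is available for sensitivity checks.

Stress bookkeeping follows the cytometry convention: shear rate
gamma = (V1 - V0)/a_p with V1 the mean flow velocity in the constriction,
V0 the cell (centroid) velocity and a_p the cell diameter; shear stress
tau = gamma * eta; shear force F = tau * (cell area / 2).  Forces are per
unit depth (2D line-force convention); multiply by the 20 um channel depth
for a 3D-equivalent value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError
from .config import ValidationError

__all__ = [
    "ShapeMetrics",
    "StressSummary",
    "deformation_index",
    "shear_rate",
    "shear_stress",
    "shear_force",
]


@dataclass(frozen=True)
class ShapeMetrics:
    DI: float
    long_axis: float
    short_axis: float
    circularity: float
    area: float
    perimeter: float


@dataclass(frozen=True)
class StressSummary:
    gamma: float       # 1/s
    tau: float         # Pa
    F_shear: float     # N/m (per unit depth)


def _polygon_moments(poly: np.ndarray):
    """Area, centroid and central second moments of a closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * A)
    cy = ((y + yn) * cross).sum() / (6.0 * A)
    Ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    Iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    Ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # central moments
    Ixx -= A * cx * cx
    Iyy -= A * cy * cy
    Ixy -= A * cx * cy
    return A, (cx, cy), Ixx, Iyy, Ixy


def deformation_index(contour: np.ndarray, method: str = "inertia") -> ShapeMetrics:
    """Shape metrics of a simple closed polygon (vertices (N, 2), un-closed).

    ``method="inertia"`` (default): axes of the inertia-equivalent ellipse,
    DI = sqrt(lambda_max / lambda_min) of the normalized second-moment
    tensor.  ``method="bbox"``: side ratio of the minimum rotated rectangle.
    """
    poly = np.asarray(contour, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 8:
        raise GeometryError("contour must be (N>=8, 2)")
    shp = Polygon(poly)
    if not shp.is_valid or shp.area <= 0:
        raise GeometryError("contour is self-intersecting or degenerate")
    A, _, Ixx, Iyy, Ixy = _polygon_moments(poly)
    if A < 0:  # clockwise input
        A, Ixx, Iyy, Ixy = -A, -Ixx, -Iyy, -Ixy
    M = np.array([[Ixx, Ixy], [Ixy, Iyy]]) / A
    lam = np.linalg.eigvalsh(M)
    lam = np.clip(lam, 1e-300, None)
    if method == "inertia":
        di = float(np.sqrt(lam[1] / lam[0]))
        long_axis = 4.0 * float(np.sqrt(lam[1]))
        short_axis = 4.0 * float(np.sqrt(lam[0]))
    elif method == "bbox":
        rect = shp.minimum_rotated_rectangle
        pts = np.asarray(rect.exterior.coords)[:-1]
        s1 = np.linalg.norm(pts[1] - pts[0])
        s2 = np.linalg.norm(pts[2] - pts[1])
        long_axis, short_axis = max(s1, s2), max(min(s1, s2), 1e-300)
        di = float(long_axis / short_axis)
    else:
        raise ValueError(f"unknown method {method!r}")
    perim = float(shp.exterior.length)
    circ = float(4.0 * np.pi * A / perim ** 2)
    return ShapeMetrics(DI=di, long_axis=long_axis, short_axis=short_axis,
                        circularity=min(circ, 1.0), area=float(A), perimeter=perim)


def shear_rate(V1: float, V0: float, a_p: float) -> float:
    """gamma = (V1 - V0) / a_p, with a_p the cell diameter (SI)."""
    if a_p <= 0:
        raise ValidationError("cell diameter a_p must be > 0")
    return (V1 - V0) / a_p


def shear_stress(gamma: float, eta: float) -> float:
    """tau = gamma * eta."""
    if eta <= 0:
        raise ValidationError("viscosity must be > 0")
    return gamma * eta


def shear_force(tau: float, cell_area: float) -> float:
    """Shear force F = tau * (cell area / 2), per unit depth (N/m)."""
    if cell_area <= 0:
        raise ValidationError("cell_area must be > 0")
    return tau * cell_area / 2.0


def stress_summary(V1: float, V0: float, a_p: float, eta: float,
                   cell_area: float) -> StressSummary:
    g = shear_rate(V1, V0, a_p)
    t = shear_stress(g, eta)
    return StressSummary(gamma=g, tau=t, F_shear=shear_force(t, cell_area))
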