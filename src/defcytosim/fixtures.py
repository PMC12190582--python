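"""Synthetic inputs with independently computed truth values.

Every downstream stage (metrics, fluid diagnostics, viscoelastic
response) can be exercised without running the FSI loop: these
generators emit analytic fields, parameterized contour families that
mimic the circle-to-rounded-triangle shapes cells adopt in the channel,
and closed-form Kelvin--Voigt creep/recovery series.

Each fixture carries its own truth, computed by a code path independent
of the main implementation: closed forms where available, otherwise a
brute-force rasterized second-moment integration on a 10x denser
contour.  Fixture randomness uses one named generator with an explicit
seed; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely

from .fluid import FluidGrid, FluidState
from .solid import kv_step_response

__all__ = [
    "Fixture",
    "make_poiseuille_field",
    "make_contour",
    "make_kv_series",
]


@dataclass
class Fixture:
    name: str
    payload: dict
    truth: dict
    seed: Optional[int] = None


def make_poiseuille_field(grid: FluidGrid, u_mean: float) -> Fixture:
    """Exact plane-Poiseuille field sampled on the staggered grid.

    The parabola spans the channel width, centered on the channel axis;
    wall and out-of-channel faces are zero.
    """
    st = FluidState(
        u=np.zeros((grid.ny, grid.nx + 1)),
        v=np.zeros((grid.ny + 1, grid.nx)),
        p=np.zeros((grid.ny, grid.nx)),
    )
    yc = (np.arange(grid.ny) + 0.5) * grid.h
    mid = grid.Ly / 2.0
    rows = grid.channel_rows
    prof = 1.5 * u_mean * (1.0 - (2.0 * (yc[rows] - mid) / grid.width) ** 2)
    st.u[rows, :] = prof[:, None]
    return Fixture(
        name="poiseuille_field",
        payload={"state": st, "grid": grid},
        truth={"U_mean": u_mean, "u_max": 1.5 * u_mean},
    )


def _raster_di(poly: np.ndarray, n: int = 600) -> float:
    """Brute-force DI: rasterize the polygon and take discrete area moments.

    Independent of the polygon-moment formulas in :mod:`defcytosim.metrics`.
    """
    shp = shapely.Polygon(poly)
    xmin, ymin, xmax, ymax = shp.bounds
    dx = max(xmax - xmin, ymax - ymin) / n
    xs = np.arange(xmin + dx / 2, xmax, dx)
    ys = np.arange(ymin + dx / 2, ymax, dx)
    XX, YY = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(shp, XX.ravel(), YY.ravel())
    px, py = XX.ravel()[inside], YY.ravel()[inside]
    px = px - px.mean()
    py = py - py.mean()
    M = np.array([[np.mean(px * px), np.mean(px * py)],
                  [np.mean(px * py), np.mean(py * py)]])
    lam = np.linalg.eigvalsh(M)
    return float(np.sqrt(lam[1] / max(lam[0], 1e-300)))


def make_contour(family: str, params: Optional[dict] = None,
                 n_vertices: int = 128, seed: int = 0) -> Fixture:
    """Closed test polygon with known deformation index.

    Families: ``circle`` (radius), ``ellipse`` (a, b, angle), and the
    non-analytic ``triangle_round`` (radius, amp) and ``star`` (radius,
    amp, lobes, noise) whose truth DI comes from the dense-raster oracle.
    """
    if n_vertices < 16:
        raise ValueError("n_vertices must be >= 16")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    th_dense = np.linspace(0.0, 2.0 * np.pi, 10 * n_vertices, endpoint=False)

    def radial(fn):
        r = fn(th)
        rd = fn(th_dense)
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        dense = np.column_stack([rd * np.cos(th_dense), rd * np.sin(th_dense)])
        return poly, dense

    if family == "circle":
        R = params.get("radius", 1.0)
        poly, _ = radial(lambda t: np.full_like(t, R))
        truth = {"DI": 1.0}
    elif family == "ellipse":
        a = params.get("a", 2.0)
        b = params.get("b", 1.0)
        ang = params.get("angle", 0.0)
        x, y = a * np.cos(th), b * np.sin(th)
        c, s = np.cos(ang), np.sin(ang)
        poly = np.column_stack([c * x - s * y, s * x + c * y])
        truth = {"DI": max(a, b) / min(a, b)}
    elif family == "triangle_round":
        R = params.get("radius", 1.0)
        amp = params.get("amp", 0.15)
        poly, dense = radial(lambda t: R * (1.0 + amp * np.cos(3.0 * t)))
        truth = {"DI": _raster_di(dense)}
    elif family == "star":
        R = params.get("radius", 1.0)
        amp = params.get("amp", 0.05)
        lobes = params.get("lobes", 5)
        noise = params.get("noise", 0.0)
        coeff = rng.normal(0.0, noise, 8) if noise > 0 else np.zeros(8)

        def fn(t):
            r = R * (1.0 + amp * np.cos(lobes * t))
            for k, c in enumerate(coeff, start=2):
                r = r + R * c * np.cos(k * t + 0.7 * k)
            return r

        poly, dense = radial(fn)
        truth = {"DI": _raster_di(dense)}
    else:
        raise ValueError(f"unknown contour family {family!r}")
    return Fixture(name=f"contour_{family}", payload={"contour": poly},
                   truth=truth, seed=seed)


def make_kv_series(sigma0: float, E: float, tau_r: float, t_grid,
                   t_off: Optional[float] = None) -> Fixture:
    """Kelvin--Voigt creep (and optional recovery) strain series.

    Loading: eps(t) = (sigma0/E)(1 - e^{-t/tau_r}).  If ``t_off`` is given,
    the load is removed there and the strain decays as e^{-(t-t_off)/tau_r}.
    """
    t = np.asarray(t_grid, dtype=float)
    eps = kv_step_response(sigma0, E, tau_r, np.minimum(t, t_off) if t_off else t)
    if t_off is not None:
        peak = kv_step_response(sigma0, E, tau_r, t_off)
        rec = t > t_off
        eps = np.where(rec, peak * np.exp(-(t - t_off) / tau_r), eps)
    return Fixture(
        name="kv_series",
        payload={"t": t, "strain": eps, "t_off": t_off},
        truth={
            "plateau": sigma0 / E,
            "at_tau": kv_step_response(sigma0, E, tau_r, tau_r),
            "tau_r": tau_r,
        },
    )
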