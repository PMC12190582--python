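"""Factor sweeps over the study conditions and trend-shape statistics.

The five standard sweeps vary one factor at a time around the baseline:
flow rate 20..100 uL/min (step 20), fluid viscosity 1..5 mPa.s (step 1),
cell diameter 8..16 um (step 2), Young's modulus 1500..7500 Pa (step
1500), relaxation time 0.04..0.64 ms (geometric, x2).  Each sweep runs
one independent transit per value and tabulates the steady mid-channel
deformation index plus the stress summary.

Trend tolerances used by the verification suite (r^2 >= 0.95 for the
"approximately linear" flow-rate and viscosity trends, 10% for the
flow-rate/viscosity equivalence) are package constants: the underlying
observations are qualitative, so the numbers here are deliberately
conservative definitions of "approximately" and "nearly".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .coupling import run_transit

__all__ = [
    "SweepSpec",
    "SweepResult",
    "DEFAULT_GRIDS",
    "run_sweep",
    "linear_trend",
    "shape_checks",
    "condition_compare",
    "SingularFitError",
]

#: Default sweep grids (surface units), one per supported factor.
DEFAULT_GRIDS: dict[str, list[float]] = {
    "flow_rate": [20.0, 40.0, 60.0, 80.0, 100.0],          # uL/min
    "fluid_viscosity": [1.0, 2.0, 3.0, 4.0, 5.0],          # mPa.s
    "diameter": [8.0, 10.0, 12.0, 14.0, 16.0],             # um
    "young_modulus": [1500.0, 3000.0, 4500.0, 6000.0, 7500.0],  # Pa
    "relaxation_time": [0.04, 0.08, 0.16, 0.32, 0.64],     # ms
}

#: Factor value ranges covered by the study; values outside require
#: extrapolate=True.
_RANGES = {
    "flow_rate": (20.0, 100.0),
    "fluid_viscosity": (1.0, 5.0),
    "diameter": (8.0, 16.0),
    "young_modulus": (1500.0, 7500.0),
    "relaxation_time": (0.04, 0.64),
}

_FACTOR_FIELD = {
    "flow_rate": ("fluid", "flow_rate"),
    "fluid_viscosity": ("fluid", "viscosity"),
    "diameter": ("cell", "diameter"),
    "young_modulus": ("cell", "young_modulus"),
    "relaxation_time": ("cell", "relaxation_time"),
}

#: Linearity threshold for the "approximately linear" flow/viscosity trends.
R2_LINEAR_MIN = 0.95
#: Relative-DI threshold for the flow-rate/viscosity equivalence check.
REL_DIFF_MAX = 0.10


class SingularFitError(ValueError):
    """OLS attempted on a constant abscissa."""


@dataclass(frozen=True)
class SweepSpec:
    """One-factor sweep definition (surface units)."""

    factor: str
    values: Optional[Sequence[float]] = None   # None -> DEFAULT_GRIDS[factor]
    held_fixed: dict = field(default_factory=dict)  # SimConfig section overrides
    extrapolate: bool = False

    def resolved_values(self) -> list[float]:
        if self.factor not in _FACTOR_FIELD:
            raise ValueError(
                f"unknown factor {self.factor!r}; one of {sorted(_FACTOR_FIELD)}"
            )
        vals = list(self.values) if self.values is not None else list(DEFAULT_GRIDS[self.factor])
        if len(vals) == 0:
            raise ValueError("sweep needs at least one value")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sweep values must be strictly increasing")
        lo, hi = _RANGES[self.factor]
        if not self.extrapolate and (vals[0] < lo - 1e-12 or vals[-1] > hi + 1e-12):
            raise ValueError(
                f"{self.factor} values outside the studied range [{lo}, {hi}]; "
                "pass extrapolate=True to override"
            )
        return vals


@dataclass
class SweepResult:
    """Tabulated steady deformation indices and trend statistics."""

    spec: SweepSpec
    table: pd.DataFrame      # columns: value, DI, tau, V0, V1, failed
    trend: Optional[dict]    # slope/intercept/r_squared/monotone/convexity

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(spec: SweepSpec, base: SimConfig,
              transit_fn: Callable = run_transit) -> SweepResult:
    """Run one transit per factor value; failed runs are flagged, not fatal."""
    base.validate()
    section, fld = _FACTOR_FIELD[spec.factor]
    rows = []
    for val in spec.resolved_values():
        overrides = {k: dict(v) for k, v in spec.held_fixed.items()}
        overrides.setdefault(section, {})[fld] = val
        cfg = base.with_overrides(**overrides)
        row = {"value": val, "DI": np.nan, "tau": np.nan, "V0": np.nan,
               "V1": np.nan, "failed": False, "error": ""}
        try:
            tr = transit_fn(cfg)
            row.update(
                DI=tr.steady_value("DI"), tau=tr.steady_value("tau"),
                V0=tr.steady_value("V0"), V1=tr.steady_value("V1"),
            )
            if not np.isfinite(row["DI"]):
                row["failed"] = True
                row["error"] = "no steady mid-channel window reached"
        except Exception as exc:  # noqa: BLE001 - row-level isolation is the contract
            row["failed"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    trend = None
    if len(ok) >= 3:
        trend = linear_trend(ok[["value", "DI"]].to_numpy())
        trend["monotone"] = _monotone_direction(ok["DI"].to_numpy())
        trend["convexity"] = _convexity(ok["value"].to_numpy(), ok["DI"].to_numpy())
    return SweepResult(spec=spec, table=table, trend=trend)


def linear_trend(table: np.ndarray) -> dict:
    """OLS of DI on the factor value: slope, intercept, r_squared."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or len(table) < 3:
        raise ValueError("need >= 3 (x, DI) rows")
    x, y = table[:, 0], table[:, 1]
    if np.ptp(x) == 0:
        raise SingularFitError("constant x: cannot fit a line")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
    }


def _monotone_direction(y: np.ndarray) -> str:
    d = np.diff(y)
    if np.all(d > 0):
        return "increasing"
    if np.all(d < 0):
        return "decreasing"
    return "none"


def _convexity(x: np.ndarray, y: np.ndarray) -> Optional[str]:
    if len(x) < 4:
        return None
    # second differences on a possibly non-uniform grid
    dd = np.diff(np.diff(y) / np.diff(x)) / (x[2:] - x[:-2])
    if np.all(dd > 0):
        return "convex"
    if np.all(dd < 0):
        return "concave"
    return "mixed"


def shape_checks(table: np.ndarray, expectation: dict) -> dict:
    """Check monotonicity/curvature expectations; report, don't raise.

    ``expectation`` keys: ``monotone`` in {"increasing", "decreasing"} and/or
    ``shape`` in {"linear", "convex", "concave"}.
    """
    table = np.asarray(table, dtype=float)
    x, y = table[:, 0], table[:, 1]
    violations = []
    report = {"monotone": _monotone_direction(y), "convexity": _convexity(x, y)}
    want_mono = expectation.get("monotone")
    if want_mono and report["monotone"] != want_mono:
        violations.append(f"expected {want_mono}, observed {report['monotone']}")
    want_shape = expectation.get("shape")
    if want_shape in ("convex", "concave"):
        if len(x) < 4:
            violations.append("convexity check needs >= 4 rows")
        elif report["convexity"] != want_shape:
            violations.append(
                f"expected {want_shape}, observed {report['convexity']}"
            )
    elif want_shape == "linear":
        r2 = linear_trend(table)["r_squared"]
        report["r_squared"] = r2
        if r2 < R2_LINEAR_MIN:
            violations.append(f"r^2 = {r2:.3f} < {R2_LINEAR_MIN}")
    report["violations"] = violations
    report["ok"] = not violations
    return report


def condition_compare(a: SimConfig, b: SimConfig,
                      transit_fn: Callable = run_transit) -> dict:
    """Steady DI under two conditions and their relative difference.

    rel_diff = |DI_a - DI_b| / mean(DI_a, DI_b).
    """
    di_a = transit_fn(a.validate()).steady_value("DI")
    di_b = transit_fn(b.validate()).steady_value("DI")
    rel = abs(di_a - di_b) / (0.5 * (di_a + di_b))
    return {"DI_a": di_a, "DI_b": di_b, "rel_diff": float(rel)}
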