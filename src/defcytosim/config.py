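"""Parameter schema, unit handling and validated simulation configs.

All user-facing quantities use the units customary in microfluidic
deformability cytometry (lengths in um, flow rates in uL/min, viscosities
in mPa.s, moduli in Pa, times in ms).  Everything downstream of this module
computes in SI; the conversion happens exactly once, through the ``*_si``
properties defined here.

The cell is an incompressible (nu = 1/2) neo-Hookean solid with a parallel
Newtonian (Kelvin--Voigt) branch.  Incompressibility fixes the shear modulus
at G = E/3; the dashpot is parameterized by the retardation time tau_r with
eta_c = tau_r * G derived, because the relaxation-time sweeps drive tau_r
directly.  A direct cell-viscosity input is accepted as an alternative, but
tau_r takes precedence when both are given.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Optional, Tuple, Union

import yaml

__all__ = [
    "ConfigError",
    "ValidationError",
    "UnsupportedMaterialError",
    "ChannelGeometry",
    "FluidProps",
    "CellProps",
    "SolverSettings",
    "SimConfig",
    "DEFAULTS",
    "UNIT_TO_SI",
    "to_si",
    "from_si",
    "load_config",
    "save_config",
    "flowrate_to_mean_velocity",
    "shear_modulus_from_young",
    "cell_viscosity_from_relaxation",
]


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or has unknown keys."""


class ValidationError(ValueError):
    """Raised when a parameter violates a documented invariant."""


class UnsupportedMaterialError(ValidationError):
    """Raised for material parameters outside the incompressible-only scope."""


# ---------------------------------------------------------------------------
# Units.  One table; every interface conversion goes through it.
# ---------------------------------------------------------------------------

UNIT_TO_SI = {
    "um": 1e-6,              # length
    "uL/min": 1e-9 / 60.0,   # volumetric flow rate -> m^3/s
    "mPa.s": 1e-3,           # dynamic viscosity -> Pa.s
    "Pa": 1.0,               # stress / modulus
    "ms": 1e-3,              # time -> s
    "kg/m^3": 1.0,           # density (already SI)
}


def to_si(value: float, unit: str) -> float:
    """Convert a surface-unit value to SI."""
    return value * UNIT_TO_SI[unit]


def from_si(value: float, unit: str) -> float:
    """Convert an SI value back to the surface unit."""
    return value / UNIT_TO_SI[unit]


# ---------------------------------------------------------------------------
# Frozen defaults (single table; never duplicated elsewhere).
#
# Baseline conditions: 20 um x 20 um channel cross-section; cell diameter
# 12 um (midpoint of the 8-16 um leukocyte range), E = 1500 Pa, tau_r =
# 0.04 ms; carrier fluid 1 mPa.s aqueous (rho = 1000 kg/m^3) at 20 uL/min.
# Channel length and reservoir shape are this package's declared choices.
# ---------------------------------------------------------------------------

DEFAULTS: dict[str, dict[str, Any]] = {
    "geometry": {
        "width": 20.0,            # um, in-plane channel width
        "depth": 20.0,            # um, out-of-plane; used only for Q -> U
        "channel_length": 200.0,  # um
        "reservoir_width": 60.0,  # um
        "reservoir_length": 60.0, # um; 0 disables entry/exit reservoirs
    },
    "fluid": {
        "viscosity": 1.0,         # mPa.s
        "density": 1000.0,        # kg/m^3
        "flow_rate": 20.0,        # uL/min
    },
    "cell": {
        "diameter": 12.0,         # um
        "young_modulus": 1500.0,  # Pa
        "poisson_ratio": 0.5,     # incompressible-only
        "relaxation_time": 0.04,  # ms; Kelvin-Voigt retardation time
        "cell_viscosity": None,   # mPa.s; alternative input, tau_r wins
        "initial_center": None,   # (x, y) um; None -> release-point rule
    },
    "solver": {
        "grid_spacing": None,     # um; None -> width/20
        "time_step": "auto",      # s or "auto"
        "cfl_limit": 0.5,
        "max_time": None,         # ms; None -> transit-time estimate
        "output_stride": 20,      # steps between trajectory samples
        "steady_tolerance": 1e-3,
        "mesh_edge": None,        # um; None -> min(h, diameter/10)
        "seed": 0,                # fixtures only; the FSI loop is deterministic
    },
}


# ---------------------------------------------------------------------------
# Elementary material/flow conversions (exposed as module operations).
# ---------------------------------------------------------------------------

def flowrate_to_mean_velocity(Q: float, geometry: "ChannelGeometry") -> float:
    """Mean inlet velocity U = Q / (width * depth), SI in and out.

    The 3D volumetric rate is divided by the full rectangular cross-section
    to obtain the mean velocity imposed on the 2D plane.
    """
    if geometry.width <= 0 or geometry.depth <= 0:
        raise ValidationError("geometry.width/depth must be positive")
    if Q < 0:
        raise ValidationError("flow_rate must be >= 0")
    return Q / (geometry.width_m * geometry.depth_m)


def shear_modulus_from_young(E: float, nu: float = 0.5) -> float:
    """G = E / (2(1+nu)); incompressible-only, so nu must be 1/2 (G = E/3)."""
    if E <= 0:
        raise ValidationError("young_modulus must be > 0")
    if abs(nu - 0.5) > 1e-12:
        raise UnsupportedMaterialError(
            f"poisson_ratio must be 0.5 (incompressible-only module), got {nu}"
        )
    return E / 3.0


def cell_viscosity_from_relaxation(tau_r: float, G: float) -> float:
    """Kelvin-Voigt dashpot viscosity eta_c = tau_r * G (SI)."""
    if tau_r < 0:
        raise ValidationError("relaxation_time must be >= 0")
    if G <= 0:
        raise ValidationError("shear modulus must be > 0")
    return tau_r * G


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGeometry:
    """Channel + entry/exit reservoir outline; surface units um."""

    width: float = DEFAULTS["geometry"]["width"]
    depth: float = DEFAULTS["geometry"]["depth"]
    channel_length: float = DEFAULTS["geometry"]["channel_length"]
    reservoir_width: float = DEFAULTS["geometry"]["reservoir_width"]
    reservoir_length: float = DEFAULTS["geometry"]["reservoir_length"]

    def validate(self) -> None:
        for name in ("width", "depth", "channel_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"geometry.{name} must be > 0")
        if self.reservoir_length < 0 or self.reservoir_width <= 0:
            raise ValidationError("geometry.reservoir dimensions must be >= 0 / > 0")
        if self.reservoir_length > 0 and self.reservoir_width < self.width:
            raise ValidationError(
                f"geometry.reservoir_width ({self.reservoir_width} um) must be >= "
                f"channel width ({self.width} um)"
            )

    # SI accessors
    @property
    def width_m(self) -> float:
        return to_si(self.width, "um")

    @property
    def depth_m(self) -> float:
        return to_si(self.depth, "um")

    @property
    def channel_length_m(self) -> float:
        return to_si(self.channel_length, "um")

    @property
    def reservoir_width_m(self) -> float:
        return to_si(self.reservoir_width, "um")

    @property
    def reservoir_length_m(self) -> float:
        return to_si(self.reservoir_length, "um")

    @property
    def has_reservoirs(self) -> bool:
        return self.reservoir_length > 0

    @property
    def domain_length_m(self) -> float:
        return self.channel_length_m + 2 * self.reservoir_length_m

    @property
    def domain_height_m(self) -> float:
        return self.reservoir_width_m if self.has_reservoirs else self.width_m


@dataclass(frozen=True)
class FluidProps:
    """Carrier fluid: Newtonian, incompressible."""

    viscosity: float = DEFAULTS["fluid"]["viscosity"]      # mPa.s
    density: float = DEFAULTS["fluid"]["density"]          # kg/m^3
    flow_rate: float = DEFAULTS["fluid"]["flow_rate"]      # uL/min

    def validate(self) -> None:
        if self.viscosity <= 0:
            raise ValidationError("fluid.viscosity must be > 0")
        if self.density <= 0:
            raise ValidationError("fluid.density must be > 0")
        if self.flow_rate < 0:
            raise ValidationError("fluid.flow_rate must be >= 0")

    @property
    def viscosity_si(self) -> float:
        return to_si(self.viscosity, "mPa.s")

    @property
    def flow_rate_si(self) -> float:
        return to_si(self.flow_rate, "uL/min")


@dataclass(frozen=True)
class CellProps:
    """Incompressible neo-Hookean / Kelvin-Voigt cell."""

    diameter: float = DEFAULTS["cell"]["diameter"]                # um
    young_modulus: float = DEFAULTS["cell"]["young_modulus"]      # Pa
    poisson_ratio: float = DEFAULTS["cell"]["poisson_ratio"]
    relaxation_time: Optional[float] = DEFAULTS["cell"]["relaxation_time"]  # ms
    cell_viscosity: Optional[float] = DEFAULTS["cell"]["cell_viscosity"]    # mPa.s
    initial_center: Optional[Tuple[float, float]] = DEFAULTS["cell"]["initial_center"]

    def validate(self, geometry: Optional[ChannelGeometry] = None) -> None:
        if self.diameter <= 0:
            raise ValidationError("cell.diameter must be > 0")
        if geometry is not None and self.diameter >= geometry.width:
            raise ValidationError(
                f"cell.diameter ({self.diameter} um) must be < channel width "
                f"({geometry.width} um)"
            )
        if self.young_modulus <= 0:
            raise ValidationError("cell.young_modulus must be > 0")
        if abs(self.poisson_ratio - 0.5) > 1e-12:
            raise UnsupportedMaterialError(
                "cell.poisson_ratio must be 0.5 (incompressible-only)"
            )
        if self.relaxation_time is not None and self.relaxation_time < 0:
            raise ValidationError("cell.relaxation_time must be >= 0")
        if self.cell_viscosity is not None and self.cell_viscosity < 0:
            raise ValidationError("cell.cell_viscosity must be >= 0")
        if self.relaxation_time is None and self.cell_viscosity is None:
            raise ValidationError(
                "cell needs relaxation_time or cell_viscosity (both None)"
            )

    @property
    def diameter_si(self) -> float:
        return to_si(self.diameter, "um")

    @property
    def shear_modulus(self) -> float:
        """G = E/3 (Pa), from incompressibility."""
        return shear_modulus_from_young(self.young_modulus, self.poisson_ratio)

    @property
    def relaxation_time_si(self) -> float:
        """Effective retardation time tau_r (s); derived from eta_c if needed."""
        if self.relaxation_time is not None:
            return to_si(self.relaxation_time, "ms")
        return to_si(self.cell_viscosity, "mPa.s") / self.shear_modulus

    @property
    def cell_viscosity_si(self) -> float:
        """Effective dashpot viscosity eta_c (Pa.s); tau_r wins when both set."""
        if self.relaxation_time is not None:
            return cell_viscosity_from_relaxation(
                to_si(self.relaxation_time, "ms"), self.shear_modulus
            )
        return to_si(self.cell_viscosity, "mPa.s")


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs; everything has a documented default."""

    grid_spacing: Optional[float] = DEFAULTS["solver"]["grid_spacing"]  # um
    time_step: Union[str, float] = DEFAULTS["solver"]["time_step"]      # s | "auto"
    cfl_limit: float = DEFAULTS["solver"]["cfl_limit"]
    max_time: Optional[float] = DEFAULTS["solver"]["max_time"]          # ms
    output_stride: int = DEFAULTS["solver"]["output_stride"]
    steady_tolerance: float = DEFAULTS["solver"]["steady_tolerance"]
    mesh_edge: Optional[float] = DEFAULTS["solver"]["mesh_edge"]        # um
    seed: int = DEFAULTS["solver"]["seed"]

    def validate(self) -> None:
        if self.grid_spacing is not None and self.grid_spacing <= 0:
            raise ValidationError("solver.grid_spacing must be > 0")
        if not (0 < self.cfl_limit <= 1):
            raise ValidationError("solver.cfl_limit must be in (0, 1]")
        if self.steady_tolerance <= 0:
            raise ValidationError("solver.steady_tolerance must be > 0")
        if self.output_stride < 1:
            raise ValidationError("solver.output_stride must be >= 1")
        if isinstance(self.time_step, str) and self.time_step != "auto":
            raise ValidationError("solver.time_step must be a number or 'auto'")


@dataclass(frozen=True)
class SimConfig:
    """Full, validated parameter set for one transit simulation."""

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    fluid: FluidProps = field(default_factory=FluidProps)
    cell: CellProps = field(default_factory=CellProps)
    solver: SolverSettings = field(default_factory=SolverSettings)

    def validate(self) -> "SimConfig":
        self.geometry.validate()
        self.fluid.validate()
        self.cell.validate(self.geometry)
        self.solver.validate()
        return self

    # ---- derived quantities (SI) -----------------------------------------
    @property
    def mean_velocity(self) -> float:
        """Mean streamwise velocity in the straight channel (m/s)."""
        return flowrate_to_mean_velocity(self.fluid.flow_rate_si, self.geometry)

    @property
    def grid_spacing_si(self) -> float:
        h_um = self.solver.grid_spacing
        if h_um is None:
            h_um = self.geometry.width / 20.0
        return to_si(h_um, "um")

    @property
    def mesh_edge_si(self) -> float:
        e_um = self.solver.mesh_edge
        if e_um is None:
            e_um = min(self.geometry.width / 20.0 if self.solver.grid_spacing is None
                       else self.solver.grid_spacing,
                       self.cell.diameter / 10.0)
        return to_si(e_um, "um")

    @property
    def release_center(self) -> Tuple[float, float]:
        """Cell release point (m): on-axis, one diameter upstream of the
        constriction entrance (or at the inlet margin if reservoirs are short)."""
        if self.cell.initial_center is not None:
            x, y = self.cell.initial_center
            return (to_si(x, "um"), to_si(y, "um"))
        g = self.geometry
        r = self.cell.diameter_si / 2.0
        x = max(g.reservoir_length_m - self.cell.diameter_si, r + 2 * self.grid_spacing_si)
        y = g.domain_height_m / 2.0
        return (x, y)

    # ---- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "fluid": asdict(self.fluid),
            "cell": asdict(self.cell),
            "solver": asdict(self.solver),
        }
        ic = d["cell"]["initial_center"]
        if ic is not None:
            d["cell"]["initial_center"] = list(ic)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data or {})
        sections = {}
        section_types = {
            "geometry": ChannelGeometry,
            "fluid": FluidProps,
            "cell": CellProps,
            "solver": SolverSettings,
        }
        unknown = set(data) - set(section_types)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        for name, typ in section_types.items():
            payload = dict(data.get(name) or {})
            allowed = set(DEFAULTS[name])
            bad = set(payload) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in '{name}': {sorted(bad)}")
            if name == "cell" and "initial_center" in payload and payload["initial_center"] is not None:
                payload["initial_center"] = tuple(payload["initial_center"])
            # tau_r / eta_c precedence: a file giving only cell_viscosity opts
            # out of the default relaxation_time.
            if name == "cell" and "cell_viscosity" in payload and "relaxation_time" not in payload:
                payload["relaxation_time"] = None
            sections[name] = typ(**payload)
        return cls(**sections).validate()

    def with_overrides(self, **sections: dict) -> "SimConfig":
        """Return a copy with per-section field overrides (surface units)."""
        out = self
        for name, fields_ in sections.items():
            current = getattr(out, name)
            out = replace(out, **{name: replace(current, **fields_)})
        return out.validate()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> SimConfig:
    """Load and validate a YAML (or JSON) config file.

    Missing keys take the documented defaults; unknown keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return SimConfig.from_dict(data)


def save_config(config: SimConfig, path: Union[str, Path]) -> None:
    """Write a config back out (YAML, or JSON for a .json suffix)."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
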