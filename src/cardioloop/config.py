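"""Run configuration: one structured TOML file drives every stage.

All physical quantities are SI unless a key is given with an explicit unit
suffix; pressure-valued keys additionally accept strings like ``"7.5 mmHg"``
or ``"1000 Pa"``.  Unknown keys are rejected with a message listing every
offending key, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .materials import MMHG_TO_PA

__all__ = ["RunConfig", "load_config", "save_config", "config_from_dict"]


def _parse_pressure(v) -> float:
    if isinstance(v, (int, float)):
        return float(v)
    if isinstance(v, str):
        parts = v.split()
        if len(parts) == 2:
            mag, unit = parts
            try:
                mag = float(mag)
            except ValueError as e:
                raise ConfigurationError(f"bad pressure literal {v!r}") from e
            if unit.lower() == "mmhg":
                return mag * MMHG_TO_PA
            if unit.lower() in ("pa",):
                return mag
            if unit.lower() == "kpa":
                return mag * 1e3
        raise ConfigurationError(f"bad pressure literal {v!r} (use 'Pa'/'kPa'/'mmHg')")
    raise ConfigurationError(f"bad pressure value {v!r}")


@dataclass
class GeometryConfig:
    R: float = 0.025              # base half-width (m)
    L: float = 0.07               # apex depth (m)
    h0: float = 0.01              # wall thickness (m)
    n_seg: int = 64
    n_r: int = 8
    inlet_span: tuple = (-0.625, -0.25)
    outlet_span: tuple = (0.25, 0.5)
    valve_zone_depth: float = 0.006
    port_length_factor: float = 4.0

    def validate(self):
        for k in ("R", "L", "h0", "valve_zone_depth"):
            if getattr(self, k) <= 0:
                raise ConfigurationError(f"geometry.{k} must be positive")


@dataclass
class MaterialConfig:
    """Guccione ventricular wall constants (Pa / dimensionless)."""
    C: float = 278.0
    b_f: float = 12.0
    b_t: float = 4.8
    b_ft: float = 8.4
    K: float = 200e3
    rho0: float = 1082.0

    def validate(self):
        if self.C <= 0 or self.K <= 0 or self.rho0 <= 0:
            raise ConfigurationError("material moduli/density must be positive")


@dataclass
class ActivationConfig:
    T_peak: float = 70e3          # active stress scale (Pa)
    alpha1: float = 0.303
    alpha2: float = 0.508
    n1: float = 1.32
    n2: float = 21.9
    T_cycle: float = 1.247        # heart period (s)
    t_onset: float = 0.0

    def validate(self):
        if self.T_cycle <= 0:
            raise ConfigurationError("activation.T_cycle must be positive")
        if not (0 < self.alpha1 < self.alpha2 < 1):
            raise ConfigurationError("need 0 < alpha1 < alpha2 < 1")


@dataclass
class WallConfig:
    kappa: float = 2.0e5          # neighbor regularization (Pa/m)
    c_damp: float = 2.0e4         # damping (Pa s/m)
    p_ext: float = 0.0            # external (pericardial) pressure (Pa)
    dt: float = 1e-3              # mechanics step (s)
    n_out: int = 250              # samples stored per cycle
    activation_taper: float = 1.0  # active stress ~ sin(theta)^q; 0 disables

    def validate(self):
        if self.dt <= 0 or self.n_out < 2:
            raise ConfigurationError("wall.dt must be > 0 and n_out >= 2")


@dataclass
class CirculationConfig:
    R_mv: float = 1.2e6           # mitral resistance (Pa s / m^3)
    R_ao: float = 8.0e5           # aortic resistance (Pa s / m^3)
    R_per: float = 1.9e8          # peripheral resistance (Pa s / m^3)
    C_art: float = 1.6e-8         # arterial compliance (m^3 / Pa)
    p_atrium: float = 7.5 * MMHG_TO_PA   # preload (Pa)
    p_art0: float = 75.0 * MMHG_TO_PA    # initial arterial pressure (Pa)
    p_chamber0: float = 7.5 * MMHG_TO_PA
    K_c: float = 1e8              # stiff chamber compliance constant (Pa)

    def validate(self):
        for k in ("R_mv", "R_ao", "R_per", "C_art", "K_c"):
            if getattr(self, k) <= 0:
                raise ConfigurationError(f"circulation.{k} must be positive")


@dataclass
class FluidConfig:
    rho: float = 1055.0           # blood density (kg/m^3)
    mu: float = 0.004             # dynamic viscosity (kg/m/s)
    D: float = 1e-10              # scalar diffusivity (m^2/s)
    cfl_max: float = 0.7
    dt0: float = 1e-3             # initial step (s)
    dt_min: float = 1e-6
    dt_max: float = 5e-3

    def validate(self):
        for k in ("rho", "mu", "D", "cfl_max", "dt0", "dt_min", "dt_max"):
            if getattr(self, k) <= 0:
                raise ConfigurationError(f"fluid.{k} must be positive")
        if self.cfl_max > 1.0:
            raise ConfigurationError("fluid.cfl_max must be <= 1")


@dataclass
class ValveModelConfig:
    q_lo: float = 20.0            # blocking threshold (ml/s)
    q_hi: float = 160.0           # full-open threshold (ml/s)
    k_min: float = 1e-7           # blocked permeability (dimensionless)
    phi: float = 1.0              # porosity

    def validate(self):
        if not (0 < self.q_lo < self.q_hi):
            raise ConfigurationError("need 0 < valve.q_lo < valve.q_hi")
        if not (0 < self.k_min < 1):
            raise ConfigurationError("valve.k_min must be in (0, 1)")


@dataclass
class CouplingConfig:
    n_mech_cycles: int = 10
    n_fluid_cycles: int = 4
    max_iter: int = 3
    tol_mm: float = 0.1
    pf_window: str = "last"       # apply the factor in the last or all cycles
    pf_smooth_s: float = 0.06     # time window for the factor determination (s)

    def validate(self):
        if self.pf_window not in ("last", "all"):
            raise ConfigurationError("coupling.pf_window must be 'last' or 'all'")
        if self.n_mech_cycles < 1 or self.n_fluid_cycles < 1:
            raise ConfigurationError("cycle counts must be >= 1")


@dataclass
class OutputConfig:
    outdir: str = "out"
    vtk_every: int = 0            # write a VTK snapshot every N fluid steps (0 = off)
    quiet: bool = False

    def validate(self):
        pass


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    wall: WallConfig = field(default_factory=WallConfig)
    circulation: CirculationConfig = field(default_factory=CirculationConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    valve: ValveModelConfig = field(default_factory=ValveModelConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    rng_seed: int = 0

    def validate(self):
        for name in ("geometry", "material", "activation", "wall",
                     "circulation", "fluid", "valve", "coupling", "output"):
            getattr(self, name).validate()
        return self

    def make_geometry(self):
        from .geometry import make_chamber
        g = self.geometry
        return make_chamber(R=g.R, L=g.L, h0=g.h0, n_seg=g.n_seg,
                            inlet_span=tuple(g.inlet_span) if g.inlet_span else None,
                            outlet_span=tuple(g.outlet_span) if g.outlet_span else None,
                            valve_zone_depth=g.valve_zone_depth,
                            port_length_factor=g.port_length_factor)


_PRESSURE_KEYS = {"p_atrium", "p_art0", "p_chamber0", "p_ext"}


def _fill(cls, data: dict, path: str, errors: list):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            errors.append(f"{path}.{key}" if path else key)
            continue
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
            continue  # handled by caller
        if key in _PRESSURE_KEYS:
            val = _parse_pressure(val)
        elif isinstance(val, list):
            # an empty list encodes "no ports" (TOML has no null)
            val = tuple(val) if val else None
        kwargs[key] = val
    return kwargs


_SECTIONS = {
    "geometry": GeometryConfig, "material": MaterialConfig,
    "activation": ActivationConfig, "wall": WallConfig,
    "circulation": CirculationConfig, "fluid": FluidConfig,
    "valve": ValveModelConfig, "coupling": CouplingConfig,
    "output": OutputConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    errors: list[str] = []
    kwargs = {}
    for key, val in data.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                errors.append(key)
                continue
            sub_kwargs = _fill(_SECTIONS[key], val, key, errors)
            try:
                kwargs[key] = _SECTIONS[key](**sub_kwargs)
            except TypeError:
                errors.append(key)
        elif key == "rng_seed":
            kwargs[key] = int(val)
        else:
            errors.append(key)
    if errors:
        raise ConfigurationError(
            "unknown or invalid configuration keys: " + ", ".join(sorted(errors)))
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration; an empty file yields the
    documented defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace('"', '\\"') + '"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if v is None:
        raise ConfigurationError("cannot serialize None; omit the key instead")
    raise ConfigurationError(f"cannot serialize {type(v).__name__} to TOML")


def save_config(cfg: RunConfig, path) -> None:
    """Write a config as TOML such that load(save(cfg)) == cfg."""
    lines = [f"rng_seed = {cfg.rng_seed}", ""]
    for section, cls in _SECTIONS.items():
        lines.append(f"[{section}]")
        obj = getattr(cfg, section)
        for f in dataclasses.fields(cls):
            v = getattr(obj, f.name)
            if v is None:
                lines.append(f"{f.name} = []")   # "no ports" marker
                continue
            lines.append(f"{f.name} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
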