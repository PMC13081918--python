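"""Run configuration: validated, unit-normalizing, provenance-tracking.

Configuration is plain YAML.  Any numeric field may be given either as a
bare number (interpreted in the field's internal unit) or as a
``"value unit"`` string, e.g. ``well_depth: "5 mm"`` or
``c_inlet: "5e-5 mol/m^3"``.  All lengths/speeds/times are normalized to
SI internally; concentrations are carried in nM at the I/O boundary.
Unknown keys are rejected, and every precondition violation is reported
with the offending key name.
"""

from __future__ import annotations

import re
from typing import Annotated, Any, Literal

import yaml
from pydantic import BaseModel, BeforeValidator, ConfigDict, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "validate_config", "parse_quantity"]

# conversion factors to the internal unit of each quantity kind
_UNITS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6},
    "speed": {"m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6},
    "time": {"s": 1.0, "min": 60.0, "h": 3600.0},
    # internal concentration unit: nM
    "concentration": {"nM": 1.0, "uM": 1e3, "M": 1e9, "mol/m^3": 1e6, "mol/m3": 1e6,
                      "nmol/m^3": 1e-3, "mmol/m^3": 1e3},
    "diffusivity": {"m^2/s": 1.0, "m2/s": 1.0, "um^2/s": 1e-12, "um2/s": 1e-12},
    "density": {"kg/m^3": 1.0, "kg/m3": 1.0, "g/cm^3": 1e3},
    "viscosity": {"Pa.s": 1.0, "Pa s": 1.0, "kg/(m.s)": 1.0, "kg/(m s)": 1.0,
                  "mPa.s": 1e-3},
    "rate": {"1/s": 1.0, "1/min": 1.0 / 60.0},
}

_QUANT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(\S.*?)?\s*$")


def parse_quantity(value: Any, kind: str) -> float:
    """Normalize ``value`` (number or 'value unit' string) to the internal unit."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _QUANT_RE.match(value)
        if m:
            num, unit = m.groups()
            try:
                x = float(num)
            except ValueError as exc:
                raise ValueError(f"cannot parse quantity {value!r}") from exc
            if unit is None:
                return x
            table = _UNITS[kind]
            if unit not in table:
                raise ValueError(f"unknown {kind} unit {unit!r}")
            return x * table[unit]
    raise ValueError(f"cannot parse quantity {value!r}")


def _q(kind: str):
    return BeforeValidator(lambda v: parse_quantity(v, kind))


Length = Annotated[float, _q("length")]
Speed = Annotated[float, _q("speed")]
Time = Annotated[float, _q("time")]
Conc = Annotated[float, _q("concentration")]
Diff = Annotated[float, _q("diffusivity")]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class GeometryConfig(_Section):
    well_depth: Length = 5.0e-3
    well_diameter: Length = 5.6e-3
    organoid_diameter: Length = 1.8e-3
    organoid_center: tuple[Length, Length] | None = (1.3e-3, 2.5e-3)
    inlet_span: tuple[Length, Length] = (4.2e-3, 5.0e-3)
    outlet_span: tuple[Length, Length] = (3.6e-3, 4.4e-3)
    out_of_plane_depth: Length | None = 5.6e-3


class FluidConfig(_Section):
    density: Annotated[float, _q("density")] = 997.0
    dynamic_viscosity: Annotated[float, _q("viscosity")] = 6.92e-3
    temperature: float = 37.0


class TransportConfig(_Section):
    D_organoid: Diff = 6.5e-14
    D_medium: Diff = 4.0e-10
    c_inlet: Conc = 50.0
    pulse_period: Time = 300.0
    pulse_duration: Time = 4.0
    flow_gated: bool = True
    t_end: Time = 4000.0
    initial_concentration: Conc = 0.0
    uptake_rate: Annotated[float, _q("rate")] = 0.0
    inlet_speed: Speed = 5.0e-3
    resolution: int = 112
    store_every: Time = 600.0
    roi_diameter: Length = 0.45e-3


class RenderConfig(_Section):
    gain: float = 2.0
    offset: float = 10.0
    noise_model: Literal["none", "gaussian", "poisson-gaussian"] = "gaussian"
    noise_scale: float = 5.0
    levels: tuple[Conc, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


class SegmentationConfig(_Section):
    phantom_radius_um: float = 198.06
    ventral_fraction: float = 0.4749
    band_width_um: float = 10.0
    noise_sd: float = 0.02
    pixel_size_um: float = 1.0


class SpotConfig(_Section):
    n: int = 200
    diameter_um: float = 4.5
    coloc_max_distance_um: float = 14.0
    pax6_probability: float = 0.6
    nkx21_probability: float = 0.4
    jitter_um: float = 5.0
    frame_size_um: float = 512.0
    pixel_size_um: float = 1.0


_STAGES = ("simulate", "render", "calibrate", "quantify", "regionalize")


class RunConfig(_Section):
    """Top-level validated configuration for the pipeline."""

    geometry: GeometryConfig = GeometryConfig()
    fluid: FluidConfig = FluidConfig()
    transport: TransportConfig = TransportConfig()
    render: RenderConfig = RenderConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    spots: SpotConfig = SpotConfig()
    stages: tuple[str, ...] = _STAGES
    out_dir: str = "organoflow_out"
    seed: int = 0
    log_level: str = "INFO"
    provenance: dict[str, str] = {}

    def snapshot(self) -> dict:
        d = self.model_dump(mode="json")
        d.pop("provenance", None)
        return d


def _check(config: RunConfig) -> None:
    """Cross-field precondition checks, reported by key name."""
    g, t = config.geometry, config.transport
    checks = [
        ("geometry.well_depth", g.well_depth > 0),
        ("geometry.well_diameter", g.well_diameter > 0),
        ("geometry.organoid_diameter", g.organoid_diameter >= 0),
        ("transport.D_organoid", t.D_organoid > 0),
        ("transport.D_medium", t.D_medium > 0),
        ("transport.c_inlet", t.c_inlet >= 0),
        ("transport.pulse_duration",
         0 < t.pulse_duration <= t.pulse_period),
        ("transport.t_end", t.t_end > 0),
        ("transport.inlet_speed", t.inlet_speed >= 0),
        ("transport.resolution", t.resolution >= 8),
        ("transport.store_every", t.store_every > 0),
        ("fluid.density", config.fluid.density > 0),
        ("fluid.dynamic_viscosity", config.fluid.dynamic_viscosity > 0),
        ("segmentation.ventral_fraction",
         0 <= config.segmentation.ventral_fraction <= 1),
        ("spots.n", config.spots.n >= 0),
        ("seed", 0 <= config.seed < 2**31),
    ]
    for key, ok in checks:
        if not ok:
            raise ConfigError(f"invalid value for {key}")
    for s in config.stages:
        if s not in _STAGES:
            raise ConfigError(f"unknown stage {s!r} in stages")


def _collect_keys(raw: dict, prefix: str = "") -> list[str]:
    keys = []
    for k, v in raw.items():
        dotted = f"{prefix}{k}"
        if isinstance(v, dict):
            keys.extend(_collect_keys(v, dotted + "."))
        else:
            keys.append(dotted)
    return keys


def validate_config(raw_text: str) -> RunConfig:
    """Parse + validate YAML config text into a :class:`RunConfig`.

    Fills defaults (an empty file yields the full default run), normalizes
    units to SI/nM, records the provenance of each supplied key, and
    raises :class:`ConfigError` naming the offending key otherwise.
    """
    try:
        raw = yaml.safe_load(raw_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        config = RunConfig(**raw)
    except ValidationError as exc:
        err = exc.errors()[0]
        key = ".".join(str(p) for p in err["loc"])
        raise ConfigError(f"invalid config value for {key}: {err['msg']}") from exc
    config.provenance = {k: "user" for k in _collect_keys(raw)}
    _check(config)
    return config
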