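"""Run configuration: schema, defaults, unit conversion and validation.

Configs are YAML (JSON is accepted, being a YAML subset).  Values are
given in bedside units — millilitres, minutes, micrometres, millimetres
and g-multiples — and converted to strict SI at the boundary.  Unknown
keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    BETA_O_DEFAULT,
    CentrifugeProtocol,
    FluidPhase,
    InvalidParameterError,
    ParticleSpecies,
)
from .correlation import CorrelationCoefficients
from .geometry import CapacityError, TubeGeometry, height_from_volume
from .sweep import SweepSpec


class ConfigError(ValueError):
    """Configuration file violates the schema."""


DEFAULTS: dict = {
    "blood": {
        "hematocrit": 0.45,
        "volume_ml": 9.0,
        "wbc_fraction": BETA_O_DEFAULT,
    },
    "fluid": {
        "density_kg_m3": 1032.0,
        "viscosity_mpa_s": 1.0,
    },
    "species": {
        "rbc": {"diameter_um": 8.0, "density_kg_m3": 1125.0},
        "wbc": {"diameter_um": 10.0, "density_kg_m3": 1065.0},
        "plt": {"diameter_um": 1.0, "density_kg_m3": 1050.0},
    },
    "geometry": {
        "rotor_radius_mm": 150.0,
        "area_mm2": 120.0,
        "capacity_ml": 15.0,
        "bottom": "flat",
        "cone_height_mm": None,
        "cone_bottom_diameter_mm": None,
        "cone_top_diameter_mm": None,
    },
    "model": {
        "m_exponent": 5.0,
        "alpha_max": 0.8,
    },
    "solver": {
        "n_cells": 200,
        "cfl": 0.5,
        "eps_clear": 1.0e-3,
        "eps_packed": 1.0e-3,
    },
    "protocol": {
        "acceleration_g": 900.0,
        "time_min": 5.0,
    },
    "sweep": {
        "acceleration_min_g": 100.0,
        "acceleration_max_g": 1500.0,
        "acceleration_step_g": 20.0,
        "times_min": [2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15],
        "hematocrit_set": [0.37, 0.45, 0.52],
        "c_w_set": [1.0e-3, 1.0e-2],
    },
    "correlation": {
        "c1": -0.0122,
        "c2": 0.5128,
        "e2": 1.0,
        "e3": 1.0,
        "e4": 1.0,
    },
    "seed": 0,
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Fully resolved run configuration in SI units."""

    hematocrit: float
    whole_blood_volume: float  # m^3
    beta_o: float
    fluid: FluidPhase
    species: dict  # name -> ParticleSpecies
    geometry: TubeGeometry
    m_exponent: float
    alpha_max: float
    n_cells: int
    cfl_number: float
    eps_clear: float
    eps_packed: float
    protocol: CentrifugeProtocol
    coefficients: CorrelationCoefficients
    sweep_accelerations: np.ndarray
    sweep_times_min: list
    hematocrit_set: tuple
    c_w_set: tuple
    seed: int
    resolved: dict = field(repr=False, default_factory=dict)

    def sweep_spec(self, conical: bool = False, **overrides) -> SweepSpec:
        geometry = self.geometry
        if conical and geometry.bottom_shape == "flat":
            geometry = TubeGeometry.conical(
                rotor_radius=geometry.rotor_radius,
                area=geometry.straight_area,
                capacity=geometry.capacity,
            )
        kwargs = dict(
            geometry=geometry,
            whole_blood_volume=self.whole_blood_volume,
            hematocrit_set=self.hematocrit_set,
            c_w_set=self.c_w_set,
            acceleration_grid=self.sweep_accelerations,
            time_grid_min=tuple(self.sweep_times_min),
            rbc=self.species["rbc"],
            wbc=self.species["wbc"],
            fluid=self.fluid,
            beta_o=self.beta_o,
            m_exponent=self.m_exponent,
            alpha_max=self.alpha_max,
            n_cells=self.n_cells,
            cfl_number=self.cfl_number,
            eps_clear=self.eps_clear,
            eps_packed=self.eps_packed,
            coefficients=self.coefficients,
        )
        kwargs.update(overrides)
        return SweepSpec(**kwargs)


def _build(raw: dict) -> RunConfig:
    blood = raw["blood"]
    if not 0 < blood["hematocrit"] < 1:
        raise ConfigError("blood.hematocrit must lie in (0, 1)")
    geo = raw["geometry"]
    r_o = geo["rotor_radius_mm"] * 1e-3
    area = geo["area_mm2"] * 1e-6
    capacity = geo["capacity_ml"] * 1e-6
    if geo["bottom"] == "flat":
        geometry = TubeGeometry.flat(r_o, area, capacity)
    elif geo["bottom"] == "conical":
        geometry = TubeGeometry.conical(
            r_o,
            area,
            capacity,
            cone_height=None
            if geo["cone_height_mm"] is None
            else geo["cone_height_mm"] * 1e-3,
            cone_bottom_diameter=None
            if geo["cone_bottom_diameter_mm"] is None
            else geo["cone_bottom_diameter_mm"] * 1e-3,
            cone_top_diameter=0.0
            if geo["cone_top_diameter_mm"] is None
            else geo["cone_top_diameter_mm"] * 1e-3,
        )
    else:
        raise ConfigError(
            f"geometry.bottom must be 'flat' or 'conical', got {geo['bottom']!r}"
        )

    v_wb = blood["volume_ml"] * 1e-6
    height_from_volume(geometry, v_wb)  # raises CapacityError if overfull

    fluid = FluidPhase(
        density=raw["fluid"]["density_kg_m3"],
        viscosity=raw["fluid"]["viscosity_mpa_s"] * 1e-3,
    )
    species = {
        name: ParticleSpecies(
            name.upper(),
            diameter=spec["diameter_um"] * 1e-6,
            density=spec["density_kg_m3"],
        )
        for name, spec in raw["species"].items()
    }

    protocol = CentrifugeProtocol(
        acceleration_g=raw["protocol"]["acceleration_g"],
        spin_time=raw["protocol"]["time_min"] * 60.0,
    )
    if protocol.acceleration_g < 100.0:
        warnings.warn(
            f"acceleration {protocol.acceleration_g:g}g is below the "
            "validated range (about 100g); gravitational settling is no "
            "longer negligible there and predictions are extrapolations",
            UserWarning,
            stacklevel=3,
        )

    sw = raw["sweep"]
    accels = np.arange(
        sw["acceleration_min_g"],
        sw["acceleration_max_g"] + 0.5 * sw["acceleration_step_g"],
        sw["acceleration_step_g"],
        dtype=float,
    )
    corr = raw["correlation"]
    return RunConfig(
        hematocrit=float(blood["hematocrit"]),
        whole_blood_volume=v_wb,
        beta_o=float(blood["wbc_fraction"]),
        fluid=fluid,
        species=species,
        geometry=geometry,
        m_exponent=float(raw["model"]["m_exponent"]),
        alpha_max=float(raw["model"]["alpha_max"]),
        n_cells=int(raw["solver"]["n_cells"]),
        cfl_number=float(raw["solver"]["cfl"]),
        eps_clear=float(raw["solver"]["eps_clear"]),
        eps_packed=float(raw["solver"]["eps_packed"]),
        protocol=protocol,
        coefficients=CorrelationCoefficients(
            c1=corr["c1"], c2=corr["c2"], e2=corr["e2"], e3=corr["e3"], e4=corr["e4"]
        ),
        sweep_accelerations=accels,
        sweep_times_min=list(sw["times_min"]),
        hematocrit_set=tuple(sw["hematocrit_set"]),
        c_w_set=tuple(sw["c_w_set"]),
        seed=int(raw["seed"]),
        resolved=raw,
    )


def load_config(path: str | None = None) -> RunConfig:
    """Load, validate and unit-convert a YAML/JSON config file.

    ``None`` or an empty file yields the all-defaults configuration.
    Unknown keys raise :class:`ConfigError` with the offending path.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("top-level config must be a mapping")
        user = loaded
    try:
        raw = _merge(DEFAULTS, user)
        return _build(raw)
    except (InvalidParameterError, CapacityError):
        raise
    except (TypeError, KeyError) as exc:  # malformed values
        raise ConfigError(f"invalid configuration: {exc}") from exc
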