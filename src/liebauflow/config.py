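"""Experiment descriptors: flat key-value config files and result export.

A descriptor file captures one experimental configuration — tube geometry,
working fluid and compression protocol — as a flat YAML mapping whose keys
carry their units (``inner_diameter_mm``, ``density_kg_m3``, ...).  Values
are converted to SI on load.  Unknown keys are rejected so that unit typos
(``inner_diameter_m`` vs ``_mm``) fail loudly instead of silently scaling
a result by a thousand.

The fluid may be given either directly (``dynamic_viscosity_cp``) or as a
glycerin-water mixture (``glycerin_volume_percent`` + ``temperature_c``),
in which case the viscosity correlation of :mod:`liebauflow.physics` is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import physics
from .physics import (
    CompressionProtocol,
    FluidProperties,
    TubeGeometry,
    cp_to_pa_s,
    m3_s_to_ul_s,
    pa_s_to_cp,
)

__all__ = ["ExperimentConfig", "load_experiment", "save_experiment", "summary_row", "summary_table"]

_GEOMETRY_KEYS = {"segment_length_mm", "inner_diameter_mm", "wall_thickness_mm"}
_FLUID_KEYS = {
    "density_kg_m3",
    "dynamic_viscosity_cp",
    "glycerin_volume_percent",
    "temperature_c",
}
_PROTOCOL_KEYS = {
    "time_on_s",
    "time_off_s",
    "pincher_length_mm",
    "pincher_offset_mm",
    "occlusion_fraction",
}
_OTHER_KEYS = {"elastic_modulus_kpa", "label"}
_KNOWN_KEYS = _GEOMETRY_KEYS | _FLUID_KEYS | _PROTOCOL_KEYS | _OTHER_KEYS


@dataclass(frozen=True)
class ExperimentConfig:
    """One configuration of the pumping loop, in SI units."""

    geometry: TubeGeometry
    fluid: FluidProperties
    protocol: CompressionProtocol
    elastic_modulus: float | None = None  # Pa, of the compliant wall
    label: str = ""

    def regime(self) -> physics.WomersleyRegime:
        return physics.womersley_regime(self.geometry, self.fluid, self.protocol)


def load_experiment(path: str | Path) -> ExperimentConfig:
    """Read a flat key-value descriptor file and build an ExperimentConfig."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: descriptor must be a flat key-value mapping")
    return experiment_from_mapping(raw, source=str(path))


def experiment_from_mapping(raw: dict, source: str = "<mapping>") -> ExperimentConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown descriptor keys {sorted(unknown)}")
    missing = (_GEOMETRY_KEYS | {"time_on_s", "time_off_s"}) - set(raw)
    if missing:
        raise ValueError(f"{source}: missing required keys {sorted(missing)}")

    geometry = TubeGeometry(
        segment_length=raw["segment_length_mm"] * 1e-3,
        inner_diameter=raw["inner_diameter_mm"] * 1e-3,
        wall_thickness=raw["wall_thickness_mm"] * 1e-3,
    )
    temperature = raw.get("temperature_c", 22.0)
    if "glycerin_volume_percent" in raw:
        if "dynamic_viscosity_cp" in raw:
            raise ValueError(
                f"{source}: give dynamic_viscosity_cp or glycerin_volume_percent, not both"
            )
        fluid = FluidProperties.glycerin_water(
            raw["glycerin_volume_percent"] / 100.0,
            temperature,
            density=raw.get("density_kg_m3"),
        )
    elif "dynamic_viscosity_cp" in raw:
        fluid = FluidProperties(
            density=raw.get("density_kg_m3", 1000.0),
            dynamic_viscosity=cp_to_pa_s(raw["dynamic_viscosity_cp"]),
            temperature=temperature,
        )
    else:
        raise ValueError(
            f"{source}: fluid needs dynamic_viscosity_cp or glycerin_volume_percent"
        )
    protocol = CompressionProtocol(
        time_on=raw["time_on_s"],
        time_off=raw["time_off_s"],
        pincher_length=raw.get("pincher_length_mm", 3.5) * 1e-3,
        pincher_offset_from_junction=raw.get("pincher_offset_mm", 2.0) * 1e-3,
        occlusion_fraction=raw.get("occlusion_fraction", 1.0),
    )
    elastic = raw.get("elastic_modulus_kpa")
    return ExperimentConfig(
        geometry=geometry,
        fluid=fluid,
        protocol=protocol,
        elastic_modulus=None if elastic is None else elastic * 1e3,
        label=str(raw.get("label", "")),
    )


def save_experiment(config: ExperimentConfig, path: str | Path) -> None:
    """Write a descriptor file that round-trips through load_experiment."""
    raw: dict = {
        "segment_length_mm": config.geometry.segment_length * 1e3,
        "inner_diameter_mm": config.geometry.inner_diameter * 1e3,
        "wall_thickness_mm": config.geometry.wall_thickness * 1e3,
        "density_kg_m3": config.fluid.density,
        "dynamic_viscosity_cp": pa_s_to_cp(config.fluid.dynamic_viscosity),
        "time_on_s": config.protocol.time_on,
        "time_off_s": config.protocol.time_off,
        "pincher_length_mm": config.protocol.pincher_length * 1e3,
        "pincher_offset_mm": config.protocol.pincher_offset_from_junction * 1e3,
        "occlusion_fraction": config.protocol.occlusion_fraction,
    }
    if config.fluid.temperature is not None:
        raw["temperature_c"] = config.fluid.temperature
    if config.elastic_modulus is not None:
        raw["elastic_modulus_kpa"] = config.elastic_modulus / 1e3
    if config.label:
        raw["label"] = config.label
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def summary_row(config: ExperimentConfig) -> dict:
    """All calculator results for one configuration as one flat record.

    Units follow reporting conventions: mm for lengths, cP for viscosity,
    Hz for frequencies, m/s for the wave speed, ul/s for the peristaltic
    reference.  Wave quantities are NaN when no elastic modulus is given.
    """
    geom, fluid, protocol = config.geometry, config.fluid, config.protocol
    regime = config.regime()
    if config.elastic_modulus is not None:
        wave = physics.wave_propagation(config.elastic_modulus, geom, fluid)
        c, fn = wave.wave_speed, wave.natural_frequency
    else:
        c = fn = float("nan")
    return {
        "label": config.label,
        "segment_length_mm": geom.segment_length * 1e3,
        "inner_diameter_mm": geom.inner_diameter * 1e3,
        "wall_thickness_mm": geom.wall_thickness * 1e3,
        "density_kg_m3": fluid.density,
        "viscosity_cp": pa_s_to_cp(fluid.dynamic_viscosity),
        "frequency_hz": protocol.frequency,
        "pincher_length_mm": protocol.pincher_length * 1e3,
        "pincher_offset_mm": protocol.pincher_offset_from_junction * 1e3,
        "womersley_number": regime.womersley_number,
        "kw": regime.kw,
        "wave_speed_m_s": c,
        "natural_frequency_hz": fn,
        "peristaltic_flowrate_ul_s": m3_s_to_ul_s(physics.peristaltic_flowrate(protocol, geom)),
    }


def summary_table(configs) -> pd.DataFrame:
    """Stack summary rows for several configurations into a DataFrame."""
    return pd.DataFrame([summary_row(c) for c in configs])
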