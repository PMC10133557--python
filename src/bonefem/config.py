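"""Declarative run configuration.

A run is fully described by one YAML or JSON document with sections
``geometry``, ``material``, ``damage``, ``simulation``, ``boundary``,
``output`` and a ``seed``.  Unknown keys are rejected (typo safety) and
validation reports every offending key at once.  The fully-resolved
configuration (defaults expanded) plus its content hash are embedded in
every run artifact, so a run is reproducible from its own output.

Units are fixed project-wide: mm, N, MPa, dimensionless strain.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .fracture import SimulationConfig
from .material import DamageLaw, ElasticConstants
from .solver import BoundaryConditions

__all__ = ["RunConfig", "ConfigError", "load_config", "config_reference"]


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometrySection(_Section):
    outer_diameter: float = Field(3.5, gt=0, description="Outer diameter of the diaphysis, mm")
    wall_thickness: float = Field(0.5, gt=0, description="Cortical wall thickness, mm")
    height: float = Field(5.0, gt=0, description="Specimen height along the shaft axis, mm")
    voxel_size: float = Field(0.25, gt=0, description="Voxel / element edge length, mm")
    eccentricity: float = Field(
        0.15, ge=0, lt=1, description="Medullary-cavity offset as a fraction of the wall thickness"
    )
    thickness_noise_sd: float = Field(
        0.03, ge=0, description="SD of smooth angular wall-surface perturbations, mm"
    )


class MaterialSection(_Section):
    E_L: float = Field(13498.0, gt=0, description="Longitudinal (osteon-axis) Young's modulus, MPa")
    E_T: float = Field(11025.0, gt=0, description="Transverse Young's modulus, MPa")
    nu_LT: float = Field(0.3, gt=-1, lt=0.5, description="Longitudinal-transverse Poisson ratio")
    nu_TT: float | None = Field(None, description="Transverse Poisson ratio (default: nu_LT)")
    G_LT: float | None = Field(
        None, gt=0, description="Longitudinal shear modulus, MPa (default: E_L/(2(1+nu_LT)))"
    )


class DamageSection(_Section):
    epsilon_f: float = Field(
        0.043, gt=0, lt=1, description="Critical compressive failure strain (dimensionless)"
    )
    D_max: float = Field(0.9, gt=0, lt=1, description="Damage-variable cap")
    residual_fraction: float | None = Field(
        None, description="Modulus fraction defining element failure (must equal 1 - D_max)"
    )


class SimulationSection(_Section):
    total_displacement: float = Field(0.5, gt=0, description="Total axial compression, mm")
    n_increments: int = Field(100, ge=1, description="Number of equal displacement increments")
    criterion: Literal["min_principal", "equivalent"] = Field(
        "min_principal", description="Strain criterion driving damage"
    )
    stagger_tolerance: float = Field(
        1e-3, gt=0, description="Convergence tolerance on the per-element damage change"
    )
    max_stagger_iterations: int = Field(25, ge=1, description="Cap on stagger iterations per increment")
    stiffness_floor: float = Field(
        1e-4, gt=0, lt=1, description="Residual stiffness factor of failed elements"
    )
    load_drop_fraction: float | None = Field(
        0.2, gt=0, lt=1, description="Stop when the reaction drops this fraction below peak (null disables)"
    )
    percolation: bool = Field(True, description="Stop when failed elements percolate the specimen")


class BoundarySection(_Section):
    top_mode: Literal["stick_platen", "frictionless_platen"] = Field(
        "stick_platen",
        description="Top platen: stick (lateral fixed, shear-transmitting) or frictionless",
    )
    bottom_mode: Literal["frictionless_platen"] = Field(
        "frictionless_platen", description="Bottom platen (frictionless only)"
    )


class OutputSection(_Section):
    write_vtu: bool = Field(True, description="Write the per-element damage field as a VTU file")
    write_plots: bool = Field(False, description="Write load-displacement plots (PNG)")


class RunConfig(_Section):
    """Complete declarative description of one run or study."""

    geometry: GeometrySection = GeometrySection()
    material: MaterialSection = MaterialSection()
    damage: DamageSection = DamageSection()
    simulation: SimulationSection = SimulationSection()
    boundary: BoundarySection = BoundarySection()
    output: OutputSection = OutputSection()
    seed: int = Field(0, ge=0, description="Seed for the synthetic-specimen generator")

    # ---- resolved views -------------------------------------------------
    def resolved(self) -> dict[str, Any]:
        """Fully-expanded configuration dictionary (all defaults applied)."""
        return self.model_dump(mode="json")

    def content_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # ---- domain-object factories ---------------------------------------
    def elastic_constants(self) -> ElasticConstants:
        m = self.material
        return ElasticConstants(
            E_L=m.E_L, E_T=m.E_T, nu_LT=m.nu_LT, nu_TT=m.nu_TT, G_LT=m.G_LT
        )

    def damage_law(self) -> DamageLaw:
        d = self.damage
        return DamageLaw(
            epsilon_f=d.epsilon_f, D_max=d.D_max, residual_fraction=d.residual_fraction
        )

    def simulation_config(self) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            total_displacement=s.total_displacement,
            n_increments=s.n_increments,
            criterion=s.criterion,
            stagger_tolerance=s.stagger_tolerance,
            max_stagger_iterations=s.max_stagger_iterations,
            stiffness_floor=s.stiffness_floor,
            load_drop_fraction=s.load_drop_fraction,
            percolation=s.percolation,
        )

    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(
            applied_axial_displacement=-self.simulation.total_displacement,
            top_mode=self.boundary.top_mode,
            bottom_mode=self.boundary.bottom_mode,
        )

    def geometry_kwargs(self) -> dict[str, Any]:
        g = self.geometry
        return {
            "outer_diameter": g.outer_diameter,
            "wall_thickness": g.wall_thickness,
            "height": g.height,
            "eccentricity": g.eccentricity,
            "thickness_noise_sd": g.thickness_noise_sd,
        }


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty (or absent) file yields the all-defaults configuration.
    ``overrides`` is a nested dict merged on top of the file contents
    (used for command-line flag precedence).  All schema violations are
    reported together in the raised :class:`ConfigError`.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            data.setdefault(key, {})
            if isinstance(data[key], dict):
                data[key].update(sub)
            else:
                data[key] = sub
        else:
            data[key] = sub
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def config_reference() -> str:
    """Markdown reference of every configuration key, type and default."""
    lines = [
        "# Configuration reference",
        "",
        "Units project-wide: mm, N, MPa, dimensionless strain.",
        "",
        "| key | type | default | description |",
        "|-----|------|---------|-------------|",
    ]

    def walk(model: type[BaseModel], prefix: str) -> None:
        for name, f in model.model_fields.items():
            ann = f.annotation
            if isinstance(ann, type) and issubclass(ann, BaseModel):
                walk(ann, f"{prefix}{name}.")
                continue
            default = f.get_default(call_default_factory=True)
            if isinstance(default, BaseModel):
                walk(type(default), f"{prefix}{name}.")
                continue
            tname = getattr(ann, "__name__", str(ann)).replace("|", "\\|")
            desc = f.description or ""
            lines.append(f"| `{prefix}{name}` | {tname} | `{default}` | {desc} |")

    walk(RunConfig, "")
    return "\n".join(lines) + "\n"
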