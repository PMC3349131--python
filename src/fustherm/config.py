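"""Declarative run configuration.

A run is described by a small YAML (or JSON) document and validated against a
strict schema — unknown fields are rejected with the offending field path.
Field names carry their unit explicitly (``*_mm``, ``*_cm_per_s``,
``*_w_per_cm3``); values are converted to SI on load, which is the only place
unit conversion happens.

Example
-------
::

    scenario:
      name: counterflow_pair
    grid:
      spacing_mm: 0.5
    solver:
      dt_s: 0.05
    source:
      p0_w_per_cm3: 15.0
      fwhm_width_mm: 4.0
      fwhm_height_mm: 30.0
      focus_mm: [30.0, 30.0, 20.0]
    duration_s: 60.0
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .grid import Grid
from .materials import MaterialProperties
from .scenarios import SCENARIO_NAMES, Scenario, VesselSpec, make_scenario
from .solver import SolverConfig
from .source import SourceSpec

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VesselConfig(_Strict):
    radius_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)
    v_mean_cm_per_s: float = Field(ge=0)
    origin_mm: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    flow_sign: Literal[1, -1] = 1

    def build(self) -> VesselSpec:
        return VesselSpec(
            radius=self.radius_mm * 1e-3,
            length=self.length_mm * 1e-3,
            v_mean=self.v_mean_cm_per_s * 1e-2,
            axis_origin=tuple(v * 1e-3 for v in self.origin_mm),
            axis_direction=self.direction,
            flow_sign=self.flow_sign,
        )


class MaterialsConfig(_Strict):
    rho_t: float = 1000.0
    c_pt: float = 4000.0
    k_eff: float = 1.8
    rho_b: float = 1060.0
    c_pb: float = 3840.0
    k_b: float = 0.6
    t_core_c: float = 37.0

    def build(self) -> MaterialProperties:
        return MaterialProperties(rho_t=self.rho_t, c_pt=self.c_pt,
                                  k_eff=self.k_eff, rho_b=self.rho_b,
                                  c_pb=self.c_pb, k_b=self.k_b,
                                  t_core=self.t_core_c)


class ScenarioConfig(_Strict):
    """Either a named preset (plus overrides) or an inline description."""

    name: Optional[str] = None
    options: dict = Field(default_factory=dict)
    domain_size_mm: Optional[tuple[float, float, float]] = None
    vessels: list[VesselConfig] = Field(default_factory=list)
    materials: MaterialsConfig = Field(default_factory=MaterialsConfig)
    boundary_thickness_mm: float = 20.0

    def build(self) -> Scenario:
        if self.name is not None:
            if self.name not in SCENARIO_NAMES:
                raise ConfigError(
                    f"scenario.name: unknown preset {self.name!r}")
            return make_scenario(
                self.name,
                materials=self.materials.build(),
                boundary_thickness=self.boundary_thickness_mm * 1e-3,
                **self.options,
            )
        if self.domain_size_mm is None:
            raise ConfigError("scenario: give either 'name' or 'domain_size_mm'")
        return Scenario(
            domain_size=tuple(v * 1e-3 for v in self.domain_size_mm),
            materials=self.materials.build(),
            vessels=tuple(v.build() for v in self.vessels),
            boundary_thickness=self.boundary_thickness_mm * 1e-3,
            label="inline",
        )


class GridConfig(_Strict):
    spacing_mm: float = Field(gt=0)
    mode: Literal["3d", "axisym"] = "3d"
    radial_extent_mm: float = 30.0  # axisym only

    def build(self, scenario: Scenario) -> Grid:
        sp = self.spacing_mm * 1e-3
        if self.mode == "axisym":
            return Grid.for_cylinder(self.radial_extent_mm * 1e-3,
                                     scenario.domain_size[2], sp)
        return Grid.for_box(scenario.domain_size, sp)


class SolverSection(_Strict):
    dt_s: float = 0.05
    scheme: Literal["explicit", "implicit"] = "explicit"

    def build(self) -> SolverConfig:
        return SolverConfig(dt=self.dt_s, scheme=self.scheme)


class SourceConfig(_Strict):
    p0_w_per_cm3: float = Field(ge=0)
    fwhm_width_mm: float = Field(gt=0)
    fwhm_height_mm: float = Field(gt=0)
    focus_mm: tuple[float, float, float]

    def build(self) -> SourceSpec:
        return SourceSpec.from_clinical(self.p0_w_per_cm3, self.fwhm_width_mm,
                                        self.fwhm_height_mm, self.focus_mm)


class PlanConfig(_Strict):
    kind: Literal["random", "sequential", "spiral"]
    p0_w_per_cm3: float = 16.5
    seed: Optional[int] = None
    n_events: int = 56
    on_s: float = 20.0
    cool_s: float = 5.0
    pitch_mm: float = 2.0
    power: Literal["fixed", "variable"] = "fixed"


class RunConfig(_Strict):
    """Validated, unit-resolved description of one run."""

    scenario: ScenarioConfig
    grid: GridConfig
    solver: SolverSection = Field(default_factory=SolverSection)
    source: Optional[SourceConfig] = None
    plan: Optional[PlanConfig] = None
    duration_s: Optional[float] = None
    seed: Optional[int] = None
    snapshot_times_s: list[float] = Field(default_factory=list)
    output: Optional[str] = None

    def build_scenario(self) -> Scenario:
        return self.scenario.build()

    def build_grid(self, scenario: Optional[Scenario] = None) -> Grid:
        return self.grid.build(scenario or self.build_scenario())

    def build_solver(self) -> SolverConfig:
        return self.solver.build()

    def build_source(self) -> Optional[SourceSpec]:
        return self.source.build() if self.source else None


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises :class:`ConfigError` naming the failing field on schema
    violations.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
        log = logging.getLogger(__name__)
        for name in type(cfg).model_fields:
            if name not in cfg.model_fields_set:
                log.debug("%s: %s defaulted to %r", p, name,
                          getattr(cfg, name))
        return cfg
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"]
            for e in err.errors()
        )
        raise ConfigError(f"{p}: {locs}") from err
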