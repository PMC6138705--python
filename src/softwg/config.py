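"""Run configuration: validated, JSON-compatible, hashable.

One configuration file describes a complete run — geometry, materials,
grid/solver, sources, probes, synthetic generator and output paths.  Unknown
keys are rejected so typos fail before any compute starts, and the resolved
configuration hashes to a stable digest that output writers embed in their
headers.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError  # noqa: F401

from .bench import BenchModelParams
from .errors import ConfigurationError
from .excitation import GaussianPulseSpec, SineSpec, SourcePlacement, SquarePulseSpec
from .fdtd import GridSpec, PmlSpec, make_grid_spec
from .geometry import MaterialAssignment, Region, RegionMaterial, TubeGeometry


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    inner_diameter_mm: float = 48.0
    outer_diameter_mm: float = 96.0
    internode_length_mm: float = 240.0
    axis: int = 2

    def to_geometry(self) -> TubeGeometry:
        return TubeGeometry(
            self.inner_diameter_mm, self.outer_diameter_mm, self.internode_length_mm, self.axis
        )


class RegionConfig(_Section):
    eps_r: float
    sigma: float


class MaterialsConfig(_Section):
    inner_solution: RegionConfig = RegionConfig(eps_r=136.0, sigma=0.487)
    dielectric: RegionConfig = RegionConfig(eps_r=10.3, sigma=0.0)
    outer_solution: RegionConfig = RegionConfig(eps_r=136.0, sigma=1.454)

    def to_assignment(self) -> MaterialAssignment:
        return MaterialAssignment(
            inner_solution=RegionMaterial(self.inner_solution.eps_r, self.inner_solution.sigma),
            dielectric=RegionMaterial(self.dielectric.eps_r, self.dielectric.sigma),
            outer_solution=RegionMaterial(self.outer_solution.eps_r, self.outer_solution.sigma),
        )


class GridConfig(_Section):
    cell_size_m: float = 2e-3
    padding_cells: int = 14
    steps: int = 1000
    pml_thickness: int = 10
    pml_order: int = 3
    pml_r0: float = 1e-4
    control: bool = False
    control_region: Literal["inner_solution", "outer_solution"] = "outer_solution"

    def to_pml(self) -> PmlSpec:
        return PmlSpec(self.pml_thickness, self.pml_order, self.pml_r0)

    def to_spec(self, dims) -> GridSpec:
        return make_grid_spec(self.cell_size_m, dims, self.steps, pml=self.to_pml())

    @property
    def control_region_enum(self) -> Region:
        return (
            Region.INNER_SOLUTION
            if self.control_region == "inner_solution"
            else Region.OUTER_SOLUTION
        )


class SourceConfig(_Section):
    kind: Literal["gaussian", "sine", "square"] = "gaussian"
    placement: Literal["axial", "ring"] = "ring"
    axial_index: int | None = None
    ring_radius_mm: float | None = None
    amplitude: float = 1.0
    # gaussian
    tau_s: float = 2.40e-9
    t0_s: float = 1.92e-9
    # sine
    wavelength_m: float | None = 1.44
    frequency_hz: float | None = None
    ramp_periods: float = 3.0
    # square
    duration_s: float = 1.0e-3
    repetition_frequency_hz: float | None = 100.0
    edge_time_s: float = 2.5e-9

    def to_placement(self) -> SourcePlacement:
        return SourcePlacement(
            mode=self.placement,
            axial_index=self.axial_index,
            ring_radius_mm=self.ring_radius_mm,
        )

    def to_waveform_spec(self):
        if self.kind == "gaussian":
            return GaussianPulseSpec(self.tau_s, self.t0_s, self.amplitude)
        if self.kind == "sine":
            return SineSpec(self.wavelength_m, self.frequency_hz, self.amplitude)
        return SquarePulseSpec(
            self.duration_s, self.repetition_frequency_hz, self.amplitude, self.edge_time_s
        )


class ProbesConfig(_Section):
    points: list[tuple[int, int, int]] = Field(default_factory=list)
    quantity: str = "Emag"
    axial_monitor: bool = True
    monitor_stride: int = 4
    monitor_start_s: float = 0.0
    stations: bool = True


class SynthConfig(_Section):
    a0: float = 0.70
    cutoff_hz: float = 3.0e4
    t_sat_s: float = 3.0e-5
    noise: float = 0.02
    thickness_coeff: float = 0.15
    concentration_coeff: float = 0.05
    n_replicates: int = 1
    fine_duration_grid: bool = False
    write_example_trace: bool = True

    def to_params(self, seed: int) -> BenchModelParams:
        return BenchModelParams(
            a0=self.a0,
            cutoff_hz=self.cutoff_hz,
            t_sat_s=self.t_sat_s,
            noise=self.noise,
            thickness_coeff=self.thickness_coeff,
            concentration_coeff=self.concentration_coeff,
            seed=seed,
        )


class OutputConfig(_Section):
    directory: str = "out"


class RunConfig(_Section):
    seed: int = 0
    log_level: str = "INFO"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    materials: MaterialsConfig = Field(default_factory=MaterialsConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    source: SourceConfig = Field(default_factory=SourceConfig)
    probes: ProbesConfig = Field(default_factory=ProbesConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _set_nested(data: dict, dotted: str, raw: str) -> None:
    keys = dotted.split(".")
    node = data
    for k in keys[:-1]:
        node = node.setdefault(k, {})
    try:
        node[keys[-1]] = json.loads(raw)
    except json.JSONDecodeError:
        node[keys[-1]] = raw


def load_config(path: str | Path | None, overrides: list[str] = ()) -> RunConfig:
    """Load a JSON config file and apply ``section.key=value`` overrides."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file {p} does not exist")
        data = json.loads(p.read_text())
    for item in overrides:
        dotted, _, raw = item.partition("=")
        if not _ or not dotted:
            raise ConfigurationError(f"override {item!r} is not of the form key=value")
        _set_nested(data, dotted, raw)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
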