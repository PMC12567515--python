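"""Structured run configuration and report serialization.

One YAML file with physics/geometry/beam/pbft/bnct/io blocks plus a single
integer seed; unknown keys are rejected and validation errors are aggregated.
An empty file resolves to the full default configuration (2 MeV beam,
2×10⁷ protons/s for 10 s, 12.5/5/1.5 µm radii, 10 × 10 nm shells).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import transport
from .geometry import CellModel, DegraderSlab, DegraderStack
from .pbft import PbftConfig

SCHEMA_VERSION = "1"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhysicsBlock(_Block):
    sigma_r_barn: float = 1.0
    b10_fraction: float = 0.199
    b11_fraction: float = 0.801


class GeometryBlock(_Block):
    nucleus_radius_um: float = 5.0
    cell_radius_um: float = 12.5
    boron_sphere_radius_um: float = 1.5
    shell_count: int = 10
    shell_thickness_nm: float = 10.0
    boron_solid: bool = False

    @model_validator(mode="after")
    def _check_nesting(self):
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus_radius_um must be < cell_radius_um")
        stack = (self.boron_sphere_radius_um
                 + self.shell_count * self.shell_thickness_nm * 1e-3)
        if stack > self.nucleus_radius_um:
            raise ValueError("boron sphere plus shells must fit in the nucleus")
        return self

    def to_cell(self) -> CellModel:
        return CellModel(self.nucleus_radius_um, self.cell_radius_um,
                         self.boron_sphere_radius_um, self.shell_count,
                         self.shell_thickness_nm, self.boron_solid)


class BeamBlock(_Block):
    energy_mev: float = 2.0
    field_type: str = "square"
    field_side_um: float = 70.0
    flux_per_s: float = 2e7
    duration_s: float = 10.0
    energy_sigma_kev: float = 0.0

    def to_beam(self) -> transport.BeamSpec:
        return transport.BeamSpec(self.energy_mev, self.field_type,
                                  self.field_side_um, self.flux_per_s,
                                  self.duration_s, self.energy_sigma_kev)


class DegraderSlabBlock(_Block):
    material: str
    thickness_um: float | None = None


class DegraderBlock(_Block):
    slabs: list[DegraderSlabBlock] = Field(default_factory=list)
    exit_gap_um: float = 0.0

    def to_stack(self) -> DegraderStack | None:
        if not self.slabs:
            return None
        return DegraderStack(tuple(DegraderSlab(s.material, s.thickness_um)
                                   for s in self.slabs), self.exit_gap_um)


class PbftBlock(_Block):
    boron_mode: str = "solid_sphere"
    dissolved_ppm: float | None = None
    dissolved_path_um: float = 25.0
    alpha_energy_mev: float = 3.0
    alphas_per_reaction: int = 3
    n_proton_histories: int = 40000
    n_alpha_histories: int = 20000
    batches: int = 10


class BnctBlock(_Block):
    thermal_fluence: float = 1e12
    background_gamma_gy: float = 0.0
    hydrogen_dose_gy: float = 0.0
    ppm_list: list[float] = Field(default_factory=lambda: [0.0, 1.0, 5.0, 10.0])
    use_weighted_release: bool = True


class IoBlock(_Block):
    out_dir: str = "."
    format: str = "json"


class RunConfig(_Block):
    physics: PhysicsBlock = Field(default_factory=PhysicsBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    beam: BeamBlock = Field(default_factory=BeamBlock)
    degrader: DegraderBlock = Field(default_factory=DegraderBlock)
    pbft: PbftBlock = Field(default_factory=PbftBlock)
    bnct: BnctBlock = Field(default_factory=BnctBlock)
    io: IoBlock = Field(default_factory=IoBlock)
    seed: int = 12345

    def to_pbft_config(self) -> PbftConfig:
        return PbftConfig(
            beam=self.beam.to_beam(), cell=self.geometry.to_cell(),
            degrader=self.degrader.to_stack(),
            sigma_r_barn=self.physics.sigma_r_barn,
            boron_mode=self.pbft.boron_mode,
            dissolved_ppm=self.pbft.dissolved_ppm,
            dissolved_path_um=self.pbft.dissolved_path_um,
            alpha_energy_mev=self.pbft.alpha_energy_mev,
            alphas_per_reaction=self.pbft.alphas_per_reaction,
            n_proton_histories=self.pbft.n_proton_histories,
            n_alpha_histories=self.pbft.n_alpha_histories,
            batches=self.pbft.batches, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file → defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def write_report(report: dict, path, fmt: str = "json",
                 seed: int | None = None,
                 config: RunConfig | None = None) -> None:
    """Serialize a report dict; JSON keeps full float precision, CSV 6 sig figs.

    JSON output carries the schema version, the seed and the resolved-config
    hash so any two runs with the same inputs are byte-comparable.
    """
    path = Path(path)
    if fmt == "json":
        payload = {"schema_version": SCHEMA_VERSION, "seed": seed,
                   "config_hash": config.config_hash() if config else None}
        payload.update(report)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_jsonify))
    elif fmt == "csv":
        frame = pd.DataFrame(report if isinstance(report, list) else [report])
        for c in frame.columns:
            if frame[c].dtype.kind == "f":
                frame[c] = frame[c].map(lambda v: float(f"{v:.6g}"))
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _jsonify(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
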