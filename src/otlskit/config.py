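"""Structured, schema-validated pipeline configuration.

All acquisition and reconstruction parameters live in one auditable YAML
document.  Unknown keys are rejected (typos should fail loudly, not fall
back to defaults), and the defaults resolve to the instrument's standard
operating point: n = 1.56 solvent clearing, 800 Hz framerate, a 256 x 2048
camera ROI and 45-degree tilt.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .optics import OpticalTrain, get_medium

__all__ = ["ConfigError", "PipelineConfig", "load_config", "config_hash"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


def _build(cls, data: Mapping[str, Any] | None, where: str):
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"bad {where} block: {exc}") from exc


@dataclass(frozen=True)
class ImmersionBlock:
    medium: str | None = "ECi"
    refractive_index: float | None = None

    def resolve_n(self) -> float:
        if self.refractive_index is not None:
            return float(self.refractive_index)
        if self.medium is not None:
            return get_medium(self.medium).refractive_index
        raise ConfigError("immersion block needs a medium name or index")


@dataclass(frozen=True)
class HolderBlock:
    material: str | None = "HIVEX"
    thickness_mm: float = 1.0


@dataclass(frozen=True)
class ScanBlock:
    tilt_deg: float = 45.0
    framerate_hz: float = 800.0
    frame_interval_um: float | None = None  # None -> matched to sampling


@dataclass(frozen=True)
class TileBlock:
    lateral_pitch_um: float = 800.0
    vertical_pitch_um: float = 70.0


@dataclass(frozen=True)
class SimulatorBlock:
    n_nuclei: int = 60
    n_filaments: int = 8
    voxel_pitch_um: float = 0.8
    use_sheet: bool = True
    sheet_dof_um: float = 110.0
    read_sigma: float = 0.0
    photon_scale: float = 0.0
    attenuation_um: float | None = None  # true specimen attenuation length
    channels: tuple[str, ...] = ("nuclear", "eosin")

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class ReconstructionBlock:
    shear_tolerance: float = 1e-3
    interpolating_fallback: bool = False
    mu_um: float | None = None  # compensation schedule; None disables it
    refine: bool = True
    max_shift_vox: int = 3
    ramp_vox: int = 8
    colorize: bool = True
    stain_k_hematoxylin: tuple[float, float, float] = (0.65, 1.0, 0.85)
    stain_k_eosin: tuple[float, float, float] = (0.10, 0.80, 0.45)
    stain_beta_hematoxylin: float = 1.0
    stain_beta_eosin: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stain_k_hematoxylin",
                           tuple(self.stain_k_hematoxylin))
        object.__setattr__(self, "stain_k_eosin", tuple(self.stain_k_eosin))


@dataclass(frozen=True)
class OutputBlock:
    strip_format: str = "h5"

    def __post_init__(self) -> None:
        if self.strip_format not in ("h5", "hdf5", "tif", "tiff"):
            raise ConfigError(f"unsupported strip format {self.strip_format!r}")


@dataclass(frozen=True)
class PipelineConfig:
    optics: OpticalTrain = field(default_factory=OpticalTrain)
    immersion: ImmersionBlock = field(default_factory=ImmersionBlock)
    holder: HolderBlock = field(default_factory=HolderBlock)
    scan: ScanBlock = field(default_factory=ScanBlock)
    extent_um: tuple[float, float, float] = (40.0, 90.0, 20.0)
    tiles: TileBlock = field(default_factory=TileBlock)
    simulator: SimulatorBlock = field(default_factory=SimulatorBlock)
    reconstruction: ReconstructionBlock = field(default_factory=ReconstructionBlock)
    output: OutputBlock = field(default_factory=OutputBlock)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Build a validated config from a YAML file path or a mapping."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {version}")
    known = {"optics", "immersion", "holder", "scan", "extent_um", "tiles",
             "simulator", "reconstruction", "output"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    extent = data.get("extent_um", (40.0, 90.0, 20.0))
    if len(extent) != 3:
        raise ConfigError("extent_um must have three entries")
    return PipelineConfig(
        optics=_build(OpticalTrain, data.get("optics"), "optics"),
        immersion=_build(ImmersionBlock, data.get("immersion"), "immersion"),
        holder=_build(HolderBlock, data.get("holder"), "holder"),
        scan=_build(ScanBlock, data.get("scan"), "scan"),
        extent_um=tuple(float(v) for v in extent),
        tiles=_build(TileBlock, data.get("tiles"), "tiles"),
        simulator=_build(SimulatorBlock, data.get("simulator"), "simulator"),
        reconstruction=_build(ReconstructionBlock, data.get("reconstruction"),
                              "reconstruction"),
        output=_build(OutputBlock, data.get("output"), "output"),
        schema_version=SCHEMA_VERSION,
    )


def config_hash(config: PipelineConfig) -> str:
    """Stable content hash of the fully-resolved configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
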