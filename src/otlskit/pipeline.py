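"""End-to-end plan -> simulate -> de-skew -> refine -> fuse -> colorize runs.

One master seed drives every source of randomness; the run manifest records
the config hash, seed, per-stage timings, output paths and collected
warnings, and is written to disk even when a stage fails (recording the
failure point), so a run directory is always self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import io as otio
from .config import PipelineConfig, config_hash, load_config
from .geometry import ScanGeometry, plan_tiles, power_schedule
from .optics import field_of_view_um, sampling_um_per_px
from .phantom import make_phantom, render_dataset
from .reconstruct import (PseudoColorParams, deskew, deskew_interpolating,
                          depth_normalize, fuse, normalize_percentile,
                          pseudo_he, refine_offsets, shear_shift_per_row)
from .geometry import strip_height_um as _strip_height

__all__ = ["StageResult", "RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class StageResult:
    name: str
    status: str = "pending"  # ok | failed | skipped
    elapsed_s: float = 0.0
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[StageResult] = field(default_factory=list)
    failed_stage: str | None = None
    artifacts: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("artifacts")
        return d

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: PipelineConfig | dict | str | Path, seed: int,
                 outdir: str | Path) -> RunManifest:
    """Execute the full pipeline under one seed; returns the run manifest.

    ``config`` may be a :class:`PipelineConfig`, a plain mapping, or a path
    to a YAML file.  In-memory results (phantom, fused volumes, corrections)
    are exposed on ``manifest.artifacts`` for programmatic use; everything
    is also written under ``outdir``.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=int(seed))
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("otlskit")
    pkg_logger.addHandler(collector)

    state: dict = {}
    stages = [
        ("plan", _stage_plan),
        ("simulate", _stage_simulate),
        ("deskew", _stage_deskew),
        ("refine", _stage_refine),
        ("fuse", _stage_fuse),
        ("colorize", _stage_colorize),
    ]
    try:
        for name, fn in stages:
            result = StageResult(name=name)
            manifest.stages.append(result)
            if manifest.failed_stage is not None:
                result.status = "skipped"
                continue
            collector.messages = []
            t0 = time.perf_counter()
            try:
                fn(config, seed, outdir, state, result)
                if result.status == "pending":
                    result.status = "ok"
            except Exception as exc:
                result.status = "failed"
                result.error = f"{type(exc).__name__}: {exc}"
                manifest.failed_stage = name
                log.error("stage %s failed: %s", name, exc)
            result.elapsed_s = time.perf_counter() - t0
            result.warnings = list(collector.messages)
    finally:
        pkg_logger.removeHandler(collector)
        manifest.artifacts = state
        manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_plan(config: PipelineConfig, seed: int, outdir: Path, state: dict,
                result: StageResult) -> None:
    n = config.immersion.resolve_n()
    sampling = sampling_um_per_px(config.optics, n)
    scan = ScanGeometry.from_sampling(
        sampling, config.scan.tilt_deg, config.scan.framerate_hz,
        frame_interval_um=config.scan.frame_interval_um)
    fov_h, fov_v = field_of_view_um(config.optics, n)
    strip_h = _strip_height(fov_v, scan.tilt_deg)
    rows, cols = config.optics.roi_rows, config.optics.sensor_cols

    tau = math.radians(scan.tilt_deg)
    matched = sampling * math.cos(tau)
    shift_est = max(1, round(matched / scan.frame_interval_um))
    lead_in = (rows - 1) * shift_est
    plan = plan_tiles(config.extent_um, fov_h, strip_h,
                      config.tiles.lateral_pitch_um,
                      config.tiles.vertical_pitch_um,
                      frame_interval_um=scan.frame_interval_um,
                      lead_in_frames=lead_in)

    schedule = None
    if config.reconstruction.mu_um is not None:
        z_max = config.extent_um[2] + strip_h + 1.0
        schedule = power_schedule(
            1.0, config.reconstruction.mu_um,
            np.linspace(-1.0, z_max, 64))

    state.update(n=n, scan=scan, plan=plan, schedule=schedule,
                 rows=rows, cols=cols)
    payload = {
        "refractive_index": n,
        "sampling_um": sampling,
        "fov_h_um": fov_h,
        "fov_v_um": fov_v,
        "strip_height_um": strip_h,
        "frame_interval_um": scan.frame_interval_um,
        "stage_velocity_um_s": scan.stage_velocity_um_s,
        "exposure_ms": scan.exposure_ms,
        "plan": dataclasses.asdict(plan),
        "power_mu_um": config.reconstruction.mu_um,
    }
    path = outdir / "plan.json"
    path.write_text(json.dumps(payload, indent=2))
    result.outputs.append(str(path))


def _stage_simulate(config: PipelineConfig, seed: int, outdir: Path,
                    state: dict, result: StageResult) -> None:
    sim = config.simulator
    phantom = make_phantom(config.extent_um, sim.n_nuclei, sim.n_filaments,
                           seed=seed, voxel_pitch_um=sim.voxel_pitch_um)
    sheet = None
    if sim.use_sheet:
        from .phantom import SheetProfile
        sheet = SheetProfile(depth_of_focus_um=sim.sheet_dof_um,
                             wavelength_um=config.optics.wavelength_um,
                             n=state["n"])
    noise = None
    if sim.read_sigma > 0 or sim.photon_scale > 0:
        noise = (sim.read_sigma, sim.photon_scale)
    mu_true = sim.attenuation_um if sim.attenuation_um else math.inf

    strips, records = render_dataset(
        phantom, state["plan"], state["scan"], state["rows"], state["cols"],
        sheet=sheet, schedule=state["schedule"], mu_true_um=mu_true,
        noise=noise, seed=seed, channels=sim.channels)

    strip_dir = outdir / "strips"
    strip_dir.mkdir(exist_ok=True)
    fmt = {"h5": "h5", "hdf5": "h5", "tif": "tif", "tiff": "tif"}[
        config.output.strip_format]
    for strip in strips:
        path = otio.write_strip(strip, strip_dir / f"{strip.strip_id}.{fmt}")
        result.outputs.append(str(path))
    result.outputs.append(str(otio.write_metadata_csv(
        records, outdir / "stage_metadata.csv")))

    gt_path = outdir / "phantom.h5"
    with h5py.File(gt_path, "w") as f:
        for ch, vol in phantom.channels.items():
            f.create_dataset(ch, data=vol, compression="gzip")
        f.attrs["voxel_pitch_um"] = phantom.voxel_pitch_um
        f.attrs["extent_um"] = phantom.extent_um
    result.outputs.append(str(gt_path))

    state.update(phantom=phantom, strips=strips, records=records,
                 mu_true=mu_true)


def _stage_deskew(config: PipelineConfig, seed: int, outdir: Path,
                  state: dict, result: StageResult) -> None:
    recon = config.reconstruction
    shift = shear_shift_per_row(state["scan"], recon.shear_tolerance,
                                allow_fallback=recon.interpolating_fallback)
    tiles: dict[str, list] = {}
    for strip in state["strips"]:
        if isinstance(shift, int):
            d = deskew(strip, shift)
        else:
            d = deskew_interpolating(strip, shift)
        if state["schedule"] is not None:
            d = depth_normalize(d, state["schedule"], "divide_compensation")
        tiles.setdefault(strip.channel, []).append(d)
    state["tiles"] = tiles
    state["shift"] = shift


def _stage_refine(config: PipelineConfig, seed: int, outdir: Path,
                  state: dict, result: StageResult) -> None:
    tiles = state["tiles"]
    first_ch = next(iter(tiles))
    dstrips = tiles[first_ch]
    pitch = np.asarray(dstrips[0].voxel_pitch_um)
    origins = np.stack([np.asarray(d.origin_um) for d in dstrips])
    base = origins.min(axis=0)
    origins_vox = np.rint((origins - base) / pitch).astype(int)
    if config.reconstruction.refine and len(dstrips) > 1:
        corrections = refine_offsets(
            [d.volume for d in dstrips], origins_vox,
            max_shift_vox=config.reconstruction.max_shift_vox)
    else:
        corrections = np.zeros((len(dstrips), 3), dtype=int)
    state.update(origins_vox=origins_vox, corrections=corrections,
                 grid_base_um=base, grid_pitch_um=pitch)

    corr_um = {d.strip_id: (corrections[i] * pitch).tolist()
               for i, d in enumerate(dstrips)}
    # record matching corrections for the other channels' strips
    for ch, dlist in tiles.items():
        for i, d in enumerate(dlist):
            corr_um[d.strip_id] = (corrections[i] * pitch).tolist()
    path = otio.write_tile_xml(state["records"], corr_um, outdir / "tiles.xml")
    result.outputs.append(str(path))


def _stage_fuse(config: PipelineConfig, seed: int, outdir: Path,
                state: dict, result: StageResult) -> None:
    fused = {}
    placed = state["origins_vox"] + state["corrections"]
    for ch, dstrips in state["tiles"].items():
        fv = fuse([d.volume for d in dstrips], placed,
                  state["grid_pitch_um"], origin_um=state["grid_base_um"],
                  ramp_vox=config.reconstruction.ramp_vox,
                  masks=[d.mask for d in dstrips])
        fused[ch] = fv
        path = outdir / f"fused_{ch}.h5"
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=fv.volume, compression="gzip")
            ds.attrs["voxel_pitch_um"] = fv.voxel_pitch_um
            ds.attrs["origin_um"] = fv.origin_um
        result.outputs.append(str(path))
    state["fused"] = fused


def _stage_colorize(config: PipelineConfig, seed: int, outdir: Path,
                    state: dict, result: StageResult) -> None:
    fused = state["fused"]
    if not config.reconstruction.colorize or not {"nuclear", "eosin"} <= set(fused):
        result.status = "skipped"
        return
    recon = config.reconstruction
    params = PseudoColorParams(
        k_hematoxylin=recon.stain_k_hematoxylin,
        k_eosin=recon.stain_k_eosin,
        beta_hematoxylin=recon.stain_beta_hematoxylin,
        beta_eosin=recon.stain_beta_eosin)
    nz = fused["nuclear"].volume.shape[2]
    mid = nz // 2
    nuc = normalize_percentile(fused["nuclear"].volume[:, :, mid])
    eos = normalize_percentile(fused["eosin"].volume[:, :, mid])
    rgb = pseudo_he(nuc, eos, params)
    path = outdir / "pseudo_he_mid.tiff"
    tifffile.imwrite(path, (rgb * 255).astype(np.uint8))
    result.outputs.append(str(path))
    state["pseudo_he"] = rgb
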