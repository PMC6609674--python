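"""Synthetic specimens and the oblique stage-scan forward model.

This module is the package's test-data factory.  It builds 3-D two-channel
phantoms (nuclei plus stromal filaments, standing in for a cleared,
fluorescently counterstained tissue) and renders them into raw oblique image
strips exactly as a stage-scanned open-top light-sheet microscope would
record them: frame ``i``, row ``j``, column ``k`` of a strip samples the
world point

    x = ox + i * ds + j * s * cos(tilt)
    y = oy + k * s
    z = oz + j * s * sin(tilt)

where ``ds`` is the stage interval between frames and ``s`` the in-plane
pixel sampling.  Rendering applies Gaussian light-sheet weighting across the
sheet normal, exponential depth attenuation ``exp(-z/mu_true)``, the
instrument's power-compensation gain ``P(z)/P0``, and an optional camera
noise model (Poisson shot noise plus Gaussian read noise) before 16-bit
quantization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import GeometryError, PowerSchedule, ScanGeometry, TilePlan

__all__ = [
    "PhantomError",
    "PhantomObject",
    "Phantom",
    "SheetProfile",
    "RawStrip",
    "StripRecord",
    "make_phantom",
    "render_strip",
    "render_dataset",
    "strip_to_world",
    "world_to_strip",
]

log = logging.getLogger(__name__)


class PhantomError(ValueError):
    """Invalid phantom or rendering parameters."""


@dataclass(frozen=True)
class PhantomObject:
    """One geometric primitive with its exact (antialiased) volume integral."""

    kind: str  # "sphere" | "filament"
    channel: str
    center_um: tuple[float, float, float]
    radius_um: float
    amplitude: float
    end_um: tuple[float, float, float] | None = None
    analytic_integral: float = 0.0  # amplitude * volume, um^3


@dataclass
class Phantom:
    """Dense ground-truth intensity volumes on an isotropic-ish grid.

    ``channels`` maps channel name to a float32 array indexed ``[ix, iy, iz]``
    with grid point ``idx`` at world position ``idx * voxel_pitch_um``.
    """

    extent_um: tuple[float, float, float]
    voxel_pitch_um: tuple[float, float, float]
    channels: dict[str, np.ndarray]
    objects: list[PhantomObject] = field(default_factory=list)

    def lookup(self, channel: str, xyz_um: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world coordinates, 0 outside."""
        vol = self.channels[channel]
        pitch = np.asarray(self.voxel_pitch_um)
        coords = (np.asarray(xyz_um, dtype=float) / pitch[:, None])
        return ndimage.map_coordinates(vol, coords, order=1, mode="constant",
                                       cval=0.0, prefilter=False)


@dataclass(frozen=True)
class SheetProfile:
    """Gaussian light-sheet thickness profile.

    The waist ``w0`` and the depth of focus obey the confocal-parameter
    relation ``DOF = 2 pi w0^2 n / lambda``; give either one.  The sheet
    broadens along its propagation axis (the strip's column direction) per
    the Gaussian-beam law ``w(y) = w0 sqrt(1 + (y/zR)^2)``.
    """

    depth_of_focus_um: float = 110.0
    wavelength_um: float = 0.515
    n: float = 1.56
    waist_um: float | None = None

    def __post_init__(self) -> None:
        if self.waist_um is None:
            zr = self.depth_of_focus_um / 2.0
            w0 = math.sqrt(zr * self.wavelength_um / (math.pi * self.n))
            object.__setattr__(self, "waist_um", w0)
        else:
            dof = 2.0 * math.pi * self.waist_um**2 * self.n / self.wavelength_um
            object.__setattr__(self, "depth_of_focus_um", dof)
        if self.waist_um <= 0:
            raise PhantomError("sheet waist must be positive")

    @property
    def rayleigh_um(self) -> float:
        return self.depth_of_focus_um / 2.0

    def width_um(self, prop_offset_um: np.ndarray | float) -> np.ndarray | float:
        """Local 1/e^2 half-width at a distance from focus along propagation."""
        return self.waist_um * np.sqrt(
            1.0 + (np.asarray(prop_offset_um, dtype=float) / self.rayleigh_um) ** 2)


@dataclass
class RawStrip:
    """One sheared stage-scanned strip plus the metadata needed to de-skew it."""

    frames: np.ndarray  # uint16 [frame, row, col]
    stage_origin_um: tuple[float, float, float]
    frame_interval_um: float
    sampling_um: float
    tilt_deg: float
    channel: str
    seed: int
    strip_id: str = "s000"

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise PhantomError("strip frames must be a 3-D tensor")


@dataclass(frozen=True)
class StripRecord:
    """Per-strip stage metadata, the acquisition-side half of the contract."""

    strip_id: str
    channel: str
    y_index: int
    z_tier: int
    x_origin_um: float
    y_origin_um: float
    z_origin_um: float
    n_frames: int
    frame_interval_um: float
    sampling_um: float
    tilt_deg: float
    seed: int


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _soft_sphere_volume(r: float, s: float) -> float:
    """Exact integral of the antialiased sphere profile.

    The profile is 1 inside radius ``r - s/2`` and falls linearly to 0 at
    ``r + s/2`` (edge smoothing width ``s``, one mean voxel pitch).
    """
    a = max(r - s / 2.0, 0.0)
    return (4.0 / 3.0) * math.pi * a**3 + 4.0 * math.pi * (
        a**2 * s / 2.0 + a * s**2 / 3.0 + s**3 / 12.0)


def _soft_disk_area(r: float, s: float) -> float:
    """Exact area of the antialiased 2-D disk profile (capsule cross-section)."""
    a = max(r - s / 2.0, 0.0)
    return math.pi * (a**2 + a * s + s**2 / 3.0)


def _paint_sphere(vol: np.ndarray, pitch: np.ndarray, center: np.ndarray,
                  r: float, amp: float, s: float) -> None:
    lo = np.maximum(np.floor((center - r - s) / pitch).astype(int), 0)
    hi = np.minimum(np.ceil((center + r + s) / pitch).astype(int) + 1,
                    np.array(vol.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(lo[d], hi[d]) * pitch[d] - center[d]
                          for d in range(3)], indexing="ij")
    dist = np.sqrt(grids[0]**2 + grids[1]**2 + grids[2]**2)
    w = np.clip((r - dist) / s + 0.5, 0.0, 1.0)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (amp * w).astype(np.float32)


def _paint_capsule(vol: np.ndarray, pitch: np.ndarray, p0: np.ndarray,
                   p1: np.ndarray, r: float, amp: float, s: float) -> None:
    lo = np.maximum(np.floor((np.minimum(p0, p1) - r - s) / pitch).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + r + s) / pitch).astype(int) + 1,
                    np.array(vol.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(lo[d], hi[d]) * pitch[d]
                          for d in range(3)], indexing="ij")
    pts = np.stack(grids, axis=-1)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    nearest = p0 + t[..., None] * seg
    dist = np.linalg.norm(pts - nearest, axis=-1)
    w = np.clip((r - dist) / s + 0.5, 0.0, 1.0)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (amp * w).astype(np.float32)


def make_phantom(
    extent_um: Sequence[float],
    n_nuclei: int = 60,
    n_filaments: int = 8,
    seed: int = 0,
    voxel_pitch_um: float | Sequence[float] = 0.8,
    nucleus_radius_um: tuple[float, float] = (2.0, 4.0),
    filament_radius_um: tuple[float, float] = (0.8, 1.5),
    nucleus_amplitude: tuple[float, float] = (600.0, 1200.0),
    filament_amplitude: tuple[float, float] = (300.0, 700.0),
    nuclear_bleedthrough: float = 0.15,
    background: float = 0.0,
) -> Phantom:
    """Reproducible two-channel tissue phantom.

    Nuclei are non-overlapping antialiased spheres in the ``nuclear``
    channel (with a small bleed-through into ``eosin``); stroma is modeled
    as random filaments (capsules) in the ``eosin`` channel, so the two
    channels have partially disjoint content as in a real nuclear/eosin
    counterstain pair.
    """
    extent = np.asarray([float(v) for v in extent_um])
    if extent.shape != (3,) or np.any(extent <= 0):
        raise PhantomError("extent must be a positive 3-vector")
    pitch = np.asarray(voxel_pitch_um, dtype=float)
    if pitch.ndim == 0:
        pitch = np.repeat(pitch, 3)
    if np.any(pitch <= 0):
        raise PhantomError("voxel pitch must be positive")

    shape = tuple(int(np.floor(extent[d] / pitch[d])) + 1 for d in range(3))
    nuclear = np.full(shape, background, dtype=np.float32)
    eosin = np.full(shape, background, dtype=np.float32)
    s = float(np.mean(pitch))  # antialias width: one mean voxel pitch
    rng = np.random.default_rng(seed)
    objects: list[PhantomObject] = []

    placed: list[tuple[np.ndarray, float]] = []
    attempts = 0
    while len(placed) < n_nuclei and attempts < 50 * max(n_nuclei, 1):
        attempts += 1
        r = rng.uniform(*nucleus_radius_um)
        margin = r + s
        if np.any(extent <= 2 * margin):
            raise PhantomError("extent too small for the requested nuclei")
        c = rng.uniform(margin, extent - margin)
        if any(np.linalg.norm(c - c2) < r + r2 + s for c2, r2 in placed):
            continue
        placed.append((c, r))
        amp = rng.uniform(*nucleus_amplitude)
        _paint_sphere(nuclear, pitch, c, r, amp, s)
        vol_int = _soft_sphere_volume(r, s)
        objects.append(PhantomObject("sphere", "nuclear", tuple(c), r, amp,
                                     analytic_integral=amp * vol_int))
        if nuclear_bleedthrough > 0:
            bt = amp * nuclear_bleedthrough
            _paint_sphere(eosin, pitch, c, r, bt, s)
            objects.append(PhantomObject("sphere", "eosin", tuple(c), r, bt,
                                         analytic_integral=bt * vol_int))

    for _ in range(n_filaments):
        r = rng.uniform(*filament_radius_um)
        margin = r + s
        p0 = rng.uniform(margin, extent - margin)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.2, 0.6) * float(extent.min())
        p1 = np.clip(p0 + direction * length, margin, extent - margin)
        amp = rng.uniform(*filament_amplitude)
        _paint_capsule(eosin, pitch, p0, p1, r, amp, s)
        seg_len = float(np.linalg.norm(p1 - p0))
        vol_int = _soft_disk_area(r, s) * seg_len + _soft_sphere_volume(r, s)
        objects.append(PhantomObject("filament", "eosin", tuple(p0), r, amp,
                                     end_um=tuple(p1),
                                     analytic_integral=amp * vol_int))

    return Phantom(extent_um=tuple(extent), voxel_pitch_um=tuple(pitch),
                   channels={"nuclear": nuclear, "eosin": eosin},
                   objects=objects)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def strip_to_world(
    origin_um: Sequence[float], frame_interval_um: float, sampling_um: float,
    tilt_deg: float, i: np.ndarray, j: np.ndarray, k: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates of strip sample (frame i, row j, col k)."""
    tau = math.radians(tilt_deg)
    ox, oy, oz = origin_um
    x = ox + np.asarray(i) * frame_interval_um + np.asarray(j) * sampling_um * math.cos(tau)
    y = oy + np.asarray(k) * sampling_um
    z = oz + np.asarray(j) * sampling_um * math.sin(tau)
    return x, y, z


def world_to_strip(
    origin_um: Sequence[float], frame_interval_um: float, sampling_um: float,
    tilt_deg: float, x: np.ndarray, y: np.ndarray, z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`strip_to_world` (real-valued indices)."""
    tau = math.radians(tilt_deg)
    ox, oy, oz = origin_um
    j = (np.asarray(z) - oz) / (sampling_um * math.sin(tau))
    k = (np.asarray(y) - oy) / sampling_um
    i = (np.asarray(x) - ox - j * sampling_um * math.cos(tau)) / frame_interval_um
    return i, j, k


def render_strip(
    phantom: Phantom,
    scan: ScanGeometry,
    origin_um: Sequence[float],
    n_frames: int,
    rows: int,
    cols: int,
    sheet: SheetProfile | None = None,
    schedule: PowerSchedule | None = None,
    mu_true_um: float = math.inf,
    noise: tuple[float, float] | None = None,
    channel: str = "nuclear",
    seed: int = 0,
    strip_id: str = "s000",
    sheet_taps: int = 9,
    sheet_span: float = 2.0,
) -> RawStrip:
    """Render one oblique strip of ``n_frames`` frames of ``rows x cols`` pixels.

    ``noise`` is ``(read_sigma, photon_scale)``; ``photon_scale`` converts
    intensity counts to expected photons for Poisson shot noise (0 disables
    it).  ``mu_true_um`` is the specimen's true attenuation length,
    deliberately independent of the compensation ``schedule`` so
    mis-compensation is testable.
    """
    if n_frames <= 0 or rows <= 0 or cols <= 0:
        raise PhantomError("strip dimensions must be positive")
    if noise is not None and (noise[0] < 0 or noise[1] < 0):
        raise PhantomError("noise parameters must be non-negative")
    if abs(scan.frame_interval_um
           - scan.sampling_um * math.cos(math.radians(scan.tilt_deg))) > 1e-6:
        log.warning("scan interval %.4f um is inconsistent with sampling %.4f um "
                    "at %.1f deg tilt: de-skew will be approximate",
                    scan.frame_interval_um, scan.sampling_um, scan.tilt_deg)

    origin = np.asarray([float(v) for v in origin_um])
    extent = np.asarray(phantom.extent_um)
    # the strip must at least intersect the phantom's y/z footprint
    tau = math.radians(scan.tilt_deg)
    y_span = (origin[1], origin[1] + (cols - 1) * scan.sampling_um)
    z_span = (origin[2], origin[2] + (rows - 1) * scan.sampling_um * math.sin(tau))
    if y_span[1] < 0 or y_span[0] > extent[1] or z_span[1] < 0 or z_span[0] > extent[2]:
        raise PhantomError("tile origin places the strip entirely outside the phantom")

    i = np.arange(n_frames)[:, None, None]
    j = np.arange(rows)[None, :, None]
    k = np.arange(cols)[None, None, :]
    x, y, z = strip_to_world(origin, scan.frame_interval_um, scan.sampling_um,
                             scan.tilt_deg, i, j, k)
    x, y, z = np.broadcast_arrays(x, y, z)
    shape = x.shape

    if sheet is None:
        value = phantom.lookup(channel, np.stack(
            [x.ravel(), y.ravel(), z.ravel()])).reshape(shape)
    else:
        # Gaussian-weighted average across the sheet normal (detection axis);
        # local width broadens away from the sheet focus at the strip center.
        nhat = np.array([math.cos(tau), 0.0, math.sin(tau)])
        y_center = origin[1] + (cols - 1) * scan.sampling_um / 2.0
        width = np.asarray(sheet.width_um(y - y_center))
        offsets = np.linspace(-sheet_span, sheet_span, sheet_taps) * sheet.waist_um
        acc = np.zeros(shape)
        wsum = np.zeros(shape)
        for d in offsets:
            g = np.exp(-2.0 * d**2 / width**2)
            pos = np.stack([(x + d * nhat[0]).ravel(), y.ravel(),
                            (z + d * nhat[2]).ravel()])
            acc += g * phantom.lookup(channel, pos).reshape(shape)
            wsum += g
        value = acc / wsum

    if math.isfinite(mu_true_um):
        value = value * np.exp(-z / mu_true_um)
    if schedule is not None:
        value = value * schedule.gain(z)

    if noise is not None:
        read_sigma, photon_scale = noise
        rng = np.random.default_rng(seed)
        if photon_scale > 0:
            value = rng.poisson(np.clip(value, 0, None) * photon_scale) / photon_scale
        if read_sigma > 0:
            value = value + rng.normal(0.0, read_sigma, size=value.shape)

    quantized = np.round(value)  # round-half-even
    clipped = np.count_nonzero((quantized < 0) | (quantized > 65535))
    if clipped:
        log.warning("strip %s: %.3f%% of samples clipped at 16-bit range",
                    strip_id, 100.0 * clipped / quantized.size)
    frames = np.clip(quantized, 0, 65535).astype(np.uint16)

    return RawStrip(frames=frames, stage_origin_um=tuple(origin),
                    frame_interval_um=scan.frame_interval_um,
                    sampling_um=scan.sampling_um, tilt_deg=scan.tilt_deg,
                    channel=channel, seed=seed, strip_id=strip_id)


def render_dataset(
    phantom: Phantom,
    plan: TilePlan,
    scan: ScanGeometry,
    rows: int,
    cols: int,
    sheet: SheetProfile | None = None,
    schedule: PowerSchedule | None = None,
    mu_true_um: float = math.inf,
    noise: tuple[float, float] | None = None,
    seed: int = 0,
    channels: Sequence[str] = ("nuclear", "eosin"),
) -> tuple[list[RawStrip], list[StripRecord]]:
    """Render one strip per (y strip, z tier, channel) of a tile plan.

    Tile origins are snapped to the de-skewed voxel grid (pitches
    ``(ds, sampling, sampling*sin(tilt))``) so overlapping strips sample
    identical world points; the *snapped* origins are what the metadata
    records, keeping acquisition and reconstruction consistent.  Per-strip
    seeds derive deterministically from the master seed.
    """
    if plan.strip_length_frames <= 0:
        raise GeometryError("tile plan lacks a frame count; pass the frame "
                            "interval to plan_tiles")
    if abs(plan.fov_h_um - cols * scan.sampling_um) > 1e-6:
        raise GeometryError(
            f"plan FOV {plan.fov_h_um} um does not match {cols} columns at "
            f"{scan.sampling_um} um sampling")
    tau = math.radians(scan.tilt_deg)
    dy = scan.sampling_um
    dz = scan.sampling_um * math.sin(tau)
    x0 = -plan.lead_in_frames * scan.frame_interval_um

    strips: list[RawStrip] = []
    records: list[StripRecord] = []
    idx = 0
    for iy in range(plan.n_strips_y):
        y0 = round(iy * plan.lateral_pitch_um / dy) * dy
        for iz in range(plan.n_tiers_z):
            z0 = round(iz * plan.vertical_pitch_um / dz) * dz if dz > 0 else 0.0
            for ch in channels:
                if ch not in phantom.channels:
                    raise PhantomError(f"phantom has no channel {ch!r}")
                sub_seed = int(np.random.SeedSequence(
                    [seed, idx]).generate_state(1)[0] % (2**31))
                sid = f"y{iy:03d}_z{iz:03d}_{ch}"
                strip = render_strip(
                    phantom, scan, (x0, y0, z0), plan.strip_length_frames,
                    rows, cols, sheet=sheet, schedule=schedule,
                    mu_true_um=mu_true_um, noise=noise, channel=ch,
                    seed=sub_seed, strip_id=sid)
                strips.append(strip)
                records.append(StripRecord(
                    strip_id=sid, channel=ch, y_index=iy, z_tier=iz,
                    x_origin_um=x0, y_origin_um=y0, z_origin_um=z0,
                    n_frames=plan.strip_length_frames,
                    frame_interval_um=scan.frame_interval_um,
                    sampling_um=scan.sampling_um, tilt_deg=scan.tilt_deg,
                    seed=sub_seed))
                idx += 1
    return strips, records
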