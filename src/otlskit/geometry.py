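"""Stage-scan and tiling geometry for oblique strip acquisition.

The camera views the specimen along an axis tilted (by default 45 degrees)
from the horizontal scan direction.  Choosing the spatial interval between
successive frames as ``sampling * cos(tilt)`` makes the shear between
adjacent image rows exactly one pixel per frame, so de-skewing reduces to
integer row shifts.  Strips tile laterally (y) and vertically (z) with a
configurable pitch/overlap, and illumination power follows an exponential
depth schedule ``P(z) = P0 * exp(z / mu)`` to offset attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "ScanGeometry",
    "TilePlan",
    "PowerSchedule",
    "scan_interval_um",
    "stage_velocity_um_s",
    "strip_height_um",
    "plan_tiles",
    "power_schedule",
]


class GeometryError(ValueError):
    """Inconsistent or unphysical acquisition geometry."""


def scan_interval_um(sampling_um: float, tilt_deg: float) -> float:
    """Frame interval that yields an exact one-pixel shear per row.

    ``interval = sampling * cos(tilt)``: as the stage advances by one
    interval, the oblique image plane slides by exactly one pixel row of
    horizontal footprint, which is what makes integer-shift de-skew exact.
    """
    if sampling_um <= 0:
        raise GeometryError("sampling must be positive")
    if not 0.0 <= tilt_deg < 90.0:
        raise GeometryError(f"tilt {tilt_deg} outside [0, 90) degrees")
    return sampling_um * math.cos(math.radians(tilt_deg))


def stage_velocity_um_s(frame_interval_um: float, framerate_hz: float) -> float:
    """Constant stage speed: one frame interval per frame period."""
    if frame_interval_um < 0 or framerate_hz <= 0:
        raise GeometryError("interval must be >= 0 and framerate > 0")
    return frame_interval_um * framerate_hz


def strip_height_um(vertical_fov_um: float, tilt_deg: float) -> float:
    """Vertical (z) extent of one strip: the tilted FOV projected onto depth."""
    if vertical_fov_um < 0:
        raise GeometryError("vertical FOV must be >= 0")
    if not 0.0 <= tilt_deg < 90.0:
        raise GeometryError(f"tilt {tilt_deg} outside [0, 90) degrees")
    return vertical_fov_um * math.cos(math.radians(tilt_deg))


@dataclass(frozen=True)
class ScanGeometry:
    """Self-consistent stage-scan parameters.

    Constructed via :meth:`from_sampling`, which derives the frame interval,
    stage velocity and exposure from the in-plane sampling, tilt and
    framerate so the integer-shift de-skew condition holds by construction.
    """

    tilt_deg: float
    sampling_um: float
    framerate_hz: float
    frame_interval_um: float
    stage_velocity_um_s: float
    exposure_ms: float

    def __post_init__(self) -> None:
        expect = scan_interval_um(self.sampling_um, self.tilt_deg)
        # consistency is a soft contract: a deliberately wrong interval is a
        # legal (artifact-producing) configuration that downstream code warns on
        if self.frame_interval_um < 0:
            raise GeometryError("frame interval must be >= 0")
        if self.framerate_hz <= 0:
            raise GeometryError("framerate must be positive")
        del expect

    @classmethod
    def from_sampling(cls, sampling_um: float, tilt_deg: float = 45.0,
                      framerate_hz: float = 800.0,
                      frame_interval_um: float | None = None) -> "ScanGeometry":
        if frame_interval_um is None:
            frame_interval_um = scan_interval_um(sampling_um, tilt_deg)
        return cls(
            tilt_deg=tilt_deg,
            sampling_um=sampling_um,
            framerate_hz=framerate_hz,
            frame_interval_um=frame_interval_um,
            stage_velocity_um_s=stage_velocity_um_s(frame_interval_um, framerate_hz),
            exposure_ms=1000.0 / framerate_hz,
        )


@dataclass(frozen=True)
class TilePlan:
    """Blueprint for covering a 3-D extent with oblique strips."""

    extent_um: tuple[float, float, float]
    fov_h_um: float
    strip_height_um: float
    lateral_pitch_um: float
    lateral_overlap_frac: float
    vertical_pitch_um: float
    vertical_overlap_frac: float
    n_strips_y: int
    n_tiers_z: int
    strip_length_frames: int
    lead_in_frames: int = 0

    def y_origins_um(self) -> list[float]:
        return [i * self.lateral_pitch_um for i in range(self.n_strips_y)]

    def z_origins_um(self) -> list[float]:
        return [i * self.vertical_pitch_um for i in range(self.n_tiers_z)]


def _axis_count(extent: float, fov: float, pitch: float) -> int:
    if extent <= fov:
        return 1
    return 1 + math.ceil((extent - fov) / pitch)


def plan_tiles(
    extent_um: Sequence[float],
    fov_h_um: float,
    strip_height: float,
    lateral_pitch_um: float = 800.0,
    vertical_pitch_um: float = 70.0,
    frame_interval_um: float | None = None,
    lead_in_frames: int = 0,
) -> TilePlan:
    """Lay out strips so their union covers ``extent_um = (x, y, z)``.

    Tile origins start at 0 and advance by the pitch; the last tile may
    overhang the extent.  Overlap fractions are ``(fov - pitch) / fov`` per
    axis.  ``frame_interval_um`` (if given) sets the frame count per strip:
    ``ceil(extent_x / interval) + lead_in + 1``, where the lead-in lets every
    depth row sweep the full x extent despite the shear.
    """
    ex, ey, ez = (float(v) for v in extent_um)
    if min(ex, ey, ez) <= 0:
        raise GeometryError("extent must be positive on every axis")
    if fov_h_um <= 0 or strip_height <= 0:
        raise GeometryError("FOV dimensions must be positive")
    if lateral_pitch_um <= 0 or vertical_pitch_um <= 0:
        raise GeometryError("pitches must be positive")
    if lateral_pitch_um > fov_h_um:
        raise GeometryError(
            f"lateral pitch {lateral_pitch_um} exceeds FOV {fov_h_um}: coverage gap")
    if vertical_pitch_um > strip_height:
        raise GeometryError(
            f"vertical pitch {vertical_pitch_um} exceeds strip height "
            f"{strip_height}: coverage gap")

    if frame_interval_um is not None:
        if frame_interval_um <= 0:
            raise GeometryError("frame interval must be positive")
        frames = math.ceil(ex / frame_interval_um) + int(lead_in_frames) + 1
    else:
        frames = 0

    return TilePlan(
        extent_um=(ex, ey, ez),
        fov_h_um=fov_h_um,
        strip_height_um=strip_height,
        lateral_pitch_um=lateral_pitch_um,
        lateral_overlap_frac=(fov_h_um - lateral_pitch_um) / fov_h_um,
        vertical_pitch_um=vertical_pitch_um,
        vertical_overlap_frac=(strip_height - vertical_pitch_um) / strip_height,
        n_strips_y=_axis_count(ey, fov_h_um, lateral_pitch_um),
        n_tiers_z=_axis_count(ez, strip_height, vertical_pitch_um),
        strip_length_frames=frames,
        lead_in_frames=int(lead_in_frames),
    )


@dataclass(frozen=True)
class PowerSchedule:
    """Exponential illumination power vs depth, P(z) = P0 * exp(z / mu).

    ``attenuation_length_um`` (mu) is deliberately user-defined: it depends
    on the specimen and clearing quality.  ``math.inf`` gives a flat
    schedule (no compensation).
    """

    base_power: float
    attenuation_length_um: float
    depths_um: np.ndarray
    powers: np.ndarray

    def gain(self, z_um: np.ndarray | float) -> np.ndarray | float:
        """Relative gain P(z)/P0 at arbitrary depth."""
        return np.exp(np.asarray(z_um, dtype=float) / self.attenuation_length_um)

    def covers(self, z_min: float, z_max: float, tol: float = 1e-6) -> bool:
        return (self.depths_um.min() <= z_min + tol
                and self.depths_um.max() >= z_max - tol)


def power_schedule(p0: float, mu_um: float,
                   depths_um: Sequence[float]) -> PowerSchedule:
    """Evaluate the exponential depth-compensation schedule at given depths."""
    if p0 <= 0:
        raise GeometryError("base power must be positive")
    if mu_um <= 0:
        raise GeometryError("attenuation length mu must be positive")
    depths = np.asarray(depths_um, dtype=float)
    if depths.size == 0:
        raise GeometryError("at least one depth required")
    powers = p0 * np.exp(depths / mu_um)
    return PowerSchedule(base_power=p0, attenuation_length_um=mu_um,
                         depths_um=depths, powers=powers)
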