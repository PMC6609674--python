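"""Refractive-index-dependent imaging parameters and holder design rules.

In a multi-immersion open-top light-sheet (OTLS) microscope both objectives
sit at an oblique angle below a transparent specimen holder.  The collection
path is a non-telecentric multi-immersion design whose magnification and
numerical aperture scale linearly with the refractive index ``n`` of the
immersion medium, so pixel sampling, field of view and resolution all depend
on the clearing protocol in use.

The second concern of this module is the holder itself: a plate of thickness
``t`` whose index differs from the medium by ``dn`` introduces an optical
path difference ``dn * t`` into the oblique converging beams.  A scalar
ray-traced wavefront model of a tilted plane-parallel plate quantifies the
resulting Strehl ratio and yields the maximum tolerable holder thickness for
near-diffraction-limited imaging (Strehl > 0.8).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

__all__ = [
    "OpticsError",
    "OpticalTrain",
    "ImmersionMedium",
    "HolderSpec",
    "WavefrontResult",
    "Material",
    "MaterialTable",
    "CompatibilityRow",
    "magnification",
    "sampling_um_per_px",
    "field_of_view_um",
    "numerical_aperture",
    "plate_opd_map",
    "strehl_ratio",
    "max_thickness_mm",
    "opd_budget_for_strehl_mm",
    "compatibility",
    "load_material_table",
    "load_media",
    "get_medium",
]

REAGENT_CLASSES = frozenset({"solvent", "aqueous", "expansion"})
CHEMICAL_CLASSES = frozenset({"glass", "monomer_polymer", "fluoropolymer"})


class OpticsError(ValueError):
    """Invalid optical configuration or parameter."""


@dataclass(frozen=True)
class OpticalTrain:
    """Fixed optical constants of the detection/illumination train.

    The magnification law is ``M(n) = (tube_focal / objective_reference_focal) * n``,
    so all n-dependent quantities (sampling, field of view) derive from the
    tube lens focal length, the objective's reference focal length and the
    camera geometry.  ``na_slope_*`` encode the linear NA-vs-n laws of the
    two beam paths; they are configuration defaults, not measured constants.
    """

    tube_focal_mm: float = 165.0
    objective_reference_focal_mm: float = 17.4
    camera_pixel_pitch_um: float = 6.5
    sensor_cols: int = 2048
    roi_rows: int = 256
    wavelength_um: float = 0.515
    na_slope_illumination: float = 0.07
    na_slope_collection: float = 0.28

    def __post_init__(self) -> None:
        for name in ("tube_focal_mm", "objective_reference_focal_mm",
                     "camera_pixel_pitch_um", "wavelength_um"):
            if getattr(self, name) <= 0:
                raise OpticsError(f"{name} must be positive")
        if self.sensor_cols <= 0:
            raise OpticsError("sensor_cols must be positive")
        if self.roi_rows < 0 or self.roi_rows > 2048:
            raise OpticsError("roi_rows must be in [0, 2048]")
        for name in ("na_slope_illumination", "na_slope_collection"):
            slope = getattr(self, name)
            if not 0.0 < slope < 1.0:
                raise OpticsError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class ImmersionMedium:
    """A clearing/immersion medium, identified by refractive index.

    ``reagent_class`` groups media by chemistry (solvent, aqueous,
    expansion); it drives the chemical-compatibility rule for holder
    materials (styrene-based polymers are destroyed by organic solvents).
    """

    name: str
    refractive_index: float
    reagent_class: str | None = None
    abbe_number: float | None = None

    def __post_init__(self) -> None:
        if not 1.0 <= self.refractive_index <= 1.7:
            raise OpticsError(
                f"refractive index {self.refractive_index} outside [1.0, 1.7]")
        if self.reagent_class is not None and self.reagent_class not in REAGENT_CLASSES:
            raise OpticsError(f"unknown reagent class {self.reagent_class!r}")


@dataclass(frozen=True)
class HolderSpec:
    """A specimen holder plate: material, index and thickness."""

    material_name: str
    material_index: float
    thickness_mm: float
    chemical_class: str = "glass"

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise OpticsError("thickness_mm must be positive")
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise OpticsError(f"unknown chemical class {self.chemical_class!r}")

    def mismatch(self, medium: ImmersionMedium) -> float:
        """Index mismatch dn = n_holder - n_medium."""
        return self.material_index - medium.refractive_index


@dataclass(frozen=True)
class WavefrontResult:
    """Residual wavefront statistics after best-focus removal."""

    rms_wavefront_error_waves: float
    strehl_ratio: float
    opd_map: np.ndarray  # mm, NaN outside the pupil


@dataclass(frozen=True)
class Material:
    name: str
    chemical_class: str
    refractive_index: float
    incompatible_reagent_classes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MaterialTable:
    rows: tuple[Material, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.rows]
        if len(names) != len(set(names)):
            raise OpticsError("duplicate material names in table")
        for m in self.rows:
            if not 1.3 <= m.refractive_index <= 1.8:
                raise OpticsError(
                    f"material {m.name}: index {m.refractive_index} outside [1.3, 1.8]")
            if m.chemical_class not in CHEMICAL_CLASSES:
                raise OpticsError(
                    f"material {m.name}: unknown class {m.chemical_class!r}")
            for rc in m.incompatible_reagent_classes:
                if rc not in REAGENT_CLASSES:
                    raise OpticsError(
                        f"material {m.name}: unknown reagent class {rc!r}")

    def __iter__(self):
        return iter(self.rows)

    def get(self, name: str) -> Material:
        for m in self.rows:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class CompatibilityRow:
    material_name: str
    chemical_class: str
    dn: float
    t_max_mm: float
    chemically_compatible: bool


# ---------------------------------------------------------------------------
# n-dependent imaging constants
# ---------------------------------------------------------------------------

def magnification(train: OpticalTrain, n: float) -> float:
    """Detection magnification M(n) = (f_tube / f_ref) * n."""
    if n <= 0:
        raise OpticsError(f"refractive index must be positive, got {n}")
    return (train.tube_focal_mm / train.objective_reference_focal_mm) * n


def sampling_um_per_px(train: OpticalTrain, n: float) -> float:
    """In-plane pixel sampling at the specimen, camera_pitch / M(n)."""
    return train.camera_pixel_pitch_um / magnification(train, n)


def field_of_view_um(train: OpticalTrain, n: float) -> tuple[float, float]:
    """(horizontal, vertical) field of view for the active camera ROI.

    Horizontal spans the full sensor width; vertical spans the reduced
    rolling-shutter ROI chosen to match the light-sheet depth of focus.
    """
    s = sampling_um_per_px(train, n)
    return train.sensor_cols * s, train.roi_rows * s


def numerical_aperture(
    train: OpticalTrain, n: float,
    path: Literal["illumination", "collection"] = "collection",
) -> float:
    """NA of either beam path under the linear NA-vs-n law."""
    if n <= 0:
        raise OpticsError(f"refractive index must be positive, got {n}")
    if path == "illumination":
        slope = train.na_slope_illumination
    elif path == "collection":
        slope = train.na_slope_collection
    else:
        raise OpticsError(f"unknown path {path!r}")
    na = slope * n
    if na >= n:
        raise OpticsError(f"NA {na} >= n {n}: unphysical configuration")
    return na


# ---------------------------------------------------------------------------
# Tilted-plate wavefront model
# ---------------------------------------------------------------------------

def plate_opd_map(
    dn: float,
    t_mm: float,
    na: float,
    tilt_deg: float = 45.0,
    n_base: float = 1.45,
    pupil_samples: int = 64,
) -> np.ndarray:
    """Per-ray optical path difference through a tilted, index-mismatched plate.

    A converging cone (half-angle ``asin(na / n_base)``) crosses a
    plane-parallel plate of index ``n_base + dn`` and thickness ``t_mm``
    whose normal is tilted by ``tilt_deg`` from the chief ray.  For each ray
    the exact OPD relative to the index-matched plate is

        OPD = t * (n2 * cos(theta2) - n1 * cos(theta1)),

    with ``n1 sin(theta1) = n2 sin(theta2)`` (Snell).  This vanishes
    identically at dn = 0 and is exactly linear in ``t``; to first order it
    is linear in the product ``dn * t``, which is why a single scalar
    governs holder-induced aberration.

    Returns a ``pupil_samples x pupil_samples`` array of OPD values in mm
    with NaN outside the circular pupil.  Pupil radius maps to the sine of
    the ray angle (aplanatic convention).
    """
    if abs(dn) > 0.2:
        raise OpticsError(f"|dn| = {abs(dn)} > 0.2: outside model validity")
    if t_mm < 0:
        raise OpticsError("plate thickness must be non-negative")
    if na >= n_base:
        raise OpticsError(f"na {na} >= base index {n_base}")
    if na <= 0:
        raise OpticsError("na must be positive")
    if pupil_samples < 16:
        raise OpticsError("pupil_samples must be >= 16")

    n1 = n_base
    n2 = n_base + dn
    tau = math.radians(tilt_deg)

    ax = np.linspace(-1.0, 1.0, pupil_samples)
    if dn == 0:  # matched plate: exactly zero OPD by construction
        px, py = np.meshgrid(ax, ax, indexing="xy")
        return np.where(px * px + py * py <= 1.0, 0.0, np.nan)
    px, py = np.meshgrid(ax, ax, indexing="xy")
    r2 = px * px + py * py
    mask = r2 <= 1.0

    # ray direction: chief ray tilted by tau from the plate normal (z axis);
    # pupil radius r -> sin(beta) = (na/n1) * r about the chief direction.
    s_max = na / n1
    sin_b = s_max * np.sqrt(r2)
    cos_b = np.sqrt(1.0 - sin_b**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(r2 > 0, px / np.sqrt(r2), 0.0)
    # cos(theta1) = d . z_plate for d = cos(b) d0 + sin(b)(cphi e1 + sphi e2)
    # with d0 = (sin tau, 0, cos tau), e1 = (cos tau, 0, -sin tau), e2 = y.
    cos_t1 = cos_b * math.cos(tau) - sin_b * cphi * math.sin(tau)
    sin_t1_sq = np.clip(1.0 - cos_t1**2, 0.0, None)
    sin_t2_sq = (n1 / n2) ** 2 * sin_t1_sq
    if np.any(sin_t2_sq[mask] >= 1.0):
        raise OpticsError("total internal reflection inside the plate")
    cos_t2 = np.sqrt(1.0 - sin_t2_sq)

    opd = t_mm * (n2 * cos_t2 - n1 * cos_t1)
    opd = np.where(mask, opd, np.nan)
    return opd


_FIT_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _best_focus_residual(opd_map: np.ndarray) -> np.ndarray:
    """Remove piston, tip/tilt and defocus by least squares; return residual."""
    ny, nx = opd_map.shape
    key = (ny, nx)
    if key not in _FIT_CACHE:
        yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
                             indexing="ij")
        basis = np.stack([np.ones_like(xx), xx, yy, xx**2 + yy**2], axis=-1)
        _FIT_CACHE[key] = (xx, basis)
    _, basis = _FIT_CACHE[key]
    valid = np.isfinite(opd_map)
    a = basis[valid]
    b = opd_map[valid]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    res = b - a @ coef
    out = np.full_like(opd_map, np.nan)
    out[valid] = res
    return out


def strehl_ratio(opd_map: np.ndarray, wavelength_um: float) -> WavefrontResult:
    """Strehl ratio of an OPD map under the extended Marechal approximation.

    Piston, tip/tilt and defocus are projected out first (a refocusable
    microscope compensates them); the residual RMS wavefront error W_rms
    gives ``S = exp(-(2 pi W_rms / lambda)^2)``, clipped to [0, 1].
    """
    opd_map = np.asarray(opd_map, dtype=float)
    if opd_map.size == 0 or not np.any(np.isfinite(opd_map)):
        raise OpticsError("empty OPD map")
    if wavelength_um <= 0:
        raise OpticsError("wavelength must be positive")
    res = _best_focus_residual(opd_map)
    rms_mm = float(np.sqrt(np.nanmean(res**2)))
    w_waves = rms_mm * 1000.0 / wavelength_um  # mm -> um -> waves
    s = math.exp(-((2.0 * math.pi * w_waves) ** 2))
    s = min(max(s, 0.0), 1.0)
    return WavefrontResult(rms_wavefront_error_waves=w_waves,
                           strehl_ratio=s, opd_map=opd_map)


def max_thickness_mm(dn: float, opd_budget_mm: float = 0.002) -> float:
    """Maximum holder thickness t_max = budget / |dn| (inf for a perfect match)."""
    if opd_budget_mm < 0:
        raise OpticsError("OPD budget must be non-negative")
    if dn == 0:
        return math.inf
    return opd_budget_mm / abs(dn)


def opd_budget_for_strehl_mm(
    s_min: float = 0.8,
    na: float = 0.4,
    tilt_deg: float = 45.0,
    n_base: float = 1.45,
    wavelength_um: float = 0.515,
    pupil_samples: int = 64,
) -> float:
    """The dn*t product at which the Strehl ratio drops to ``s_min``.

    Uses the first-order linearity of the residual wavefront in dn*t: one
    map at a small probe mismatch sets the waves-per-(dn*t) slope, which is
    inverted for the target RMS from the Marechal relation.
    """
    if not 0.0 < s_min < 1.0:
        raise OpticsError("s_min must be in (0, 1)")
    probe_dn, probe_t = 1e-3, 1.0
    opd = plate_opd_map(probe_dn, probe_t, na, tilt_deg, n_base, pupil_samples)
    w_probe = strehl_ratio(opd, wavelength_um).rms_wavefront_error_waves
    w_target = math.sqrt(-math.log(s_min)) / (2.0 * math.pi)
    return (w_target / w_probe) * probe_dn * probe_t


# ---------------------------------------------------------------------------
# Material / reagent compatibility
# ---------------------------------------------------------------------------

def load_material_table() -> MaterialTable:
    """Packaged table of candidate holder materials."""
    rows = []
    text = resources.files("otlskit.data").joinpath("materials.csv").read_text()
    for rec in csv.DictReader(text.splitlines()):
        bad = frozenset(x for x in rec["incompatible_with"].split(";") if x)
        rows.append(Material(
            name=rec["name"],
            chemical_class=rec["chemical_class"],
            refractive_index=float(rec["refractive_index"]),
            incompatible_reagent_classes=bad,
        ))
    return MaterialTable(tuple(rows))


def load_media() -> tuple[ImmersionMedium, ...]:
    """Packaged registry of clearing/immersion media."""
    out = []
    text = resources.files("otlskit.data").joinpath("media.csv").read_text()
    for rec in csv.DictReader(text.splitlines()):
        out.append(ImmersionMedium(
            name=rec["name"],
            refractive_index=float(rec["refractive_index"]),
            reagent_class=rec["reagent_class"] or None,
        ))
    return tuple(out)


def get_medium(name_or_index: str | float) -> ImmersionMedium:
    """Look a medium up by name, or wrap a bare refractive index."""
    if isinstance(name_or_index, (int, float)):
        return ImmersionMedium(name=f"n={name_or_index}",
                               refractive_index=float(name_or_index))
    for m in load_media():
        if m.name.lower() == str(name_or_index).lower():
            return m
    raise KeyError(f"unknown medium {name_or_index!r}")


def compatibility(
    table: MaterialTable, medium: ImmersionMedium,
    opd_budget_mm: float = 0.002,
) -> list[CompatibilityRow]:
    """Per-material mismatch, thickness budget and chemical compatibility.

    A material is chemically incompatible when the medium's reagent class is
    in the material's incompatibility set (class-level rule: styrene-based
    polymers are destroyed by organic solvents, with per-material overrides
    carried by the packaged table).
    """
    if medium.reagent_class is None or medium.reagent_class not in REAGENT_CLASSES:
        raise OpticsError(
            f"medium {medium.name!r} has unknown reagent class "
            f"{medium.reagent_class!r}")
    out = []
    for m in table:
        dn = m.refractive_index - medium.refractive_index
        out.append(CompatibilityRow(
            material_name=m.name,
            chemical_class=m.chemical_class,
            dn=dn,
            t_max_mm=max_thickness_mm(dn, opd_budget_mm),
            chemically_compatible=medium.reagent_class
            not in m.incompatible_reagent_classes,
        ))
    return out
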