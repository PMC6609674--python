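# Methods

This note documents the models implemented in otlskit, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate about real data.

## Index-dependent imaging constants

The detection path is a non-telecentric multi-immersion design: its
magnification is *M(n) = (f_tube / f_ref) · n* with defaults
f_tube = 165 mm and f_ref = 17.4 mm, and the NA of each beam path is a
linear function of the immersion index, NA = slope · n. Pixel sampling is
`camera_pixel_pitch / M(n)` (6.5-µm pixels → 0.4394 µm/px at n = 1.56);
the horizontal field of view spans the full 2048-column sensor (≈0.9 mm)
and the vertical field the 256-row rolling-shutter ROI (≈112.5 µm), chosen
to match the light sheet's ≈110-µm depth of focus.

The NA-vs-n slopes are configuration defaults, not measured constants:
`na_slope_collection = 0.28` is a plausible value for this class of
objective, and `na_slope_illumination = 0.07` is derived so the sheet NA at
n = 1.56 is consistent with the 110-µm depth of focus through the Gaussian
confocal parameter. Both are overridable in `OpticalTrain`.

## Tilted-plate wavefront model

A holder plate of thickness *t* whose index differs from the surrounding
medium by Δn aberrates the oblique converging beams. We model this with an
exact scalar ray trace: for each ray of a cone with half-angle
asin(NA/n_base) (pupil radius mapped to the ray-angle sine), tilted 45°
from the plate normal, the optical path difference relative to a matched
plate is

    OPD = t · (n₂ cos θ₂ − n₁ cos θ₁),   n₁ sin θ₁ = n₂ sin θ₂,

which vanishes identically at Δn = 0 and is exactly linear in *t*. Piston,
tip/tilt and defocus are projected out by least squares before computing
the RMS wavefront error (a refocusable microscope compensates these
terms), and the Strehl ratio follows the extended Maréchal approximation
S = exp(−(2π·W_rms/λ)²), clipped to [0, 1]. Defaults: base index 1.45,
λ = 0.515 µm, 64 × 64 circular pupil (W_rms converges to ≪0.1% of its
256 × 256 value at this sampling).

Inverting the model for S = 0.8 gives an OPD budget of 0.0029 mm at
NA 0.30, 0.0015 mm at NA 0.40 and 0.0011 mm at NA 0.45 (45° tilt) —
the same order as the 0.002-mm rule of thumb used for holder design; the
packaged compatibility table uses 0.002 mm as its default budget. This is
a calibration-level agreement: a full vectorial model of a specific
objective would shift the constant, not the 1/|Δn| scaling of t_max.

Known asymmetry: the residual (post-defocus) wavefront is *not* exactly
even in Δn — the odd component is ≈10·Δn in relative terms (e.g. 10% at
Δn = 0.01), a property of the exact Snell trace that a first-order
Δn·t model hides. Design conclusions in the S > 0.8 regime are unaffected.

Out of scope: chromatic OPD (materials are evaluated at one design
wavelength even when Abbe numbers are known), field-edge behavior, and
lens-prescription effects.

## Acquisition geometry

With the detection axis tilted τ = 45° from the scan direction, choosing
the frame interval Δs = sampling · cos τ makes each successive frame's
image plane land exactly one pixel row over, so de-skew is an integer
relocation. At the solvent operating point: Δs = 0.3107 µm, stage speed
Δs · 800 Hz = 0.249 mm/s, exposure 1.25 ms. A strip's vertical footprint
is the tilted FOV projected onto depth (112.5 µm · cos 45° ≈ 79.5 µm).
Tiling uses pitches of 0.8 mm laterally (≈11% overlap of the 0.9-mm FOV)
and 70 µm vertically (≈12% of the strip height); tile origins start at 0
and advance by the pitch, with the last tile allowed to overhang.
Coverage counts are `1 + ceil((extent − fov)/pitch)`, and overlap
fractions `(fov − pitch)/fov`.

Illumination power follows P(z) = P₀ · exp(z/μ). μ has no default — it is
specimen-dependent and must be supplied explicitly when compensation is
enabled. Depths are measured from the holder surface, positive downward;
all indices are 0-based and physical intervals half-open.

## Phantom simulator

`make_phantom` builds a two-channel specimen: non-overlapping antialiased
spheres ("nuclei", with a 15% bleed-through into the second channel) and
random capsules ("stroma"/eosin). Each primitive's edge falls linearly
over one mean voxel pitch, and the exact integral of that softened profile
is stored per object, so total rendered intensity is checkable in closed
form. Default amplitudes (600–1200 counts for nuclei) keep noiseless
renders well inside the 16-bit range.

`render_strip` samples the phantom at the world coordinates of each
(frame, row, column) sample — x = ox + i·Δs + j·s·cos τ, y = oy + k·s,
z = oz + j·s·sin τ — by trilinear interpolation, then applies in order:

- **Sheet weighting**: a normalized Gaussian-weighted average along the
  detection axis with intensity profile exp(−2d²/w(y)²); the local width
  w(y) broadens away from the focus (strip center) per the Gaussian-beam
  law, with waist derived from the 110-µm depth of focus
  (w₀ = 2.40 µm at n = 1.56). Because frames sweep every plane, the
  normalized *total* response to a point source is position-independent;
  the Gaussian appears in the per-plane response, which is what the tests
  assert (exp(−2) at one waist off-plane, to 10% at the default tap
  density).
- **Attenuation** exp(−z/μ_true). μ_true is deliberately independent of
  the compensation schedule's μ so mis-compensation is representable.
- **Compensation gain** P(z)/P₀ when a schedule is given (hardware
  compensation baked into the counts).
- **Noise**: Poisson shot noise at a photon-per-count scale, then additive
  Gaussian read noise; both optional, seeded per strip from the master
  seed.
- **Quantization** to uint16 with round-half-even; clipping is logged with
  the clipped fraction.

`render_dataset` lays one strip per (y strip, z tier, channel). Tile
origins are snapped to the de-skewed voxel grid (Δs, s, s·sin τ) and the
snapped origins are recorded in the stage metadata. This is a deliberate
contract: the reconstruction is integer-voxel throughout, and snapping
makes overlapping strips sample identical world points, which the overlap-
consistency and round-trip tests rely on. Real stages stop at sub-voxel
positions; handling that would require sub-voxel registration and
interpolating fusion, both out of scope.

Not modeled: optical blur/aberration coupling, scattering, rolling-shutter
timing, galvo dithering, field-edge vignetting. Passing tests therefore
demonstrate geometric and radiometric self-consistency of the pipeline,
not robustness to optical artifacts of real instruments.

## Reconstruction

- **De-skew** relocates each row plane by `shift = s·cos τ / Δs` pixels
  (an integer when the interval is matched; mismatch beyond 1e-3 raises an
  "incorrect scan interval" error rather than silently interpolating — an
  explicit interpolating fallback exists behind a flag). Relocation
  conserves intensity exactly; untouched cells are zero-filled and masked.
- **Depth normalization** divides out (or applies) the schedule gain per
  z plane; the schedule must cover the volume's depth range.
- **Offset refinement** maximizes plain normalized cross-correlation on
  overlap crops (≤128³ voxels, centered) over integer shifts within
  ±max_shift_vox (default 3–4), anchors tile 0 and propagates pairwise
  shifts along a breadth-first spanning tree. Pairs whose overlap minus
  the search radius drops below 8 voxels are skipped with a warning.
  Integer-only, deterministic; no subpixel or global least-squares model.
- **Fusion** blends tiles with separable linear edge ramps (default 8
  voxels), renormalized per voxel so weights sum to 1 wherever any tile
  contributes — constants are preserved, single tiles are identities, and
  aligned overlaps are seamless. The output grid is the bounding box of
  all placed tiles; a per-voxel coverage count is kept as provenance.
- **Pseudo-H&E**: RGB_c = exp(−(β_H·I_H·k_H,c + β_E·I_E·k_E,c)) on
  intensities normalized to [0, 1] (0.5th–99.5th percentile scaling in the
  pipeline). The default stain vectors k_H = (0.65, 1.0, 0.85) and
  k_E = (0.10, 0.80, 0.45) are package conventions chosen for a plausible
  hematoxylin/eosin look and are fully configurable; quantitative use
  requires calibration against reference histology.

## Pipeline, formats, determinism

`run_pipeline` executes plan → simulate → de-skew → refine → fuse →
colorize from one schema-validated YAML config (unknown keys rejected) and
one master seed; every per-strip seed derives from it, so a fixed
(config, seed) pair reproduces bit-identical outputs. The manifest records
config hash, seed, per-stage status/timings/outputs and collected warnings
(clipping, shear mismatch, skipped overlaps), and is written even when a
stage fails. Strips live in multi-page TIFF or chunked gzip HDF5 with full
stage metadata embedded (missing metadata is a schema error); the tile
layout is a small repo-specific XML dialect (per-strip translation affine
from nominal origin + correction). The native camera format of real
instruments is proprietary and unsupported.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen as
the smallest sizes that still exercise every code path: a 3 × 2-tile,
two-channel dataset at 0.8-µm sampling (24 × 48 ROI, ~78 frames/strip)
for round trips, 50 random small strips for the de-skew oracle, and a
64 × 64 pupil for the wavefront model. The geometry/optics constants are
closed-form and independent of problem size.
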