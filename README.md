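# otlskit

A simulate-and-reconstruct toolkit for **multi-immersion open-top
light-sheet (OTLS) microscopy** of optically cleared tissue.

In an OTLS microscope both objectives sit at 45° *below* a transparent
specimen holder, like a flatbed scanner, and the whole optical train is
immersed in a medium matched to the clearing protocol (expansion n ≈ 1.33,
aqueous n ≈ 1.38–1.49, solvent n ≈ 1.51–1.56). Two things make the
computational side of such an instrument non-standard:

1. **Everything depends on the refractive index.** The detection
   magnification follows *M(n) = (165 mm / 17.4 mm) · n*, so pixel
   sampling, field of view and the NA of both beam paths change with the
   immersion medium. The holder itself is an optical element: a plate with
   index mismatch Δn and thickness *t* injects an optical path difference
   Δn·t into the oblique converging beams, and only Δn·t below a small
   budget keeps the Strehl ratio *S* above the near-diffraction-limited
   threshold 0.8 (Maréchal: *S* = exp(−(2π·W_rms/λ)²)).
2. **The volume is acquired obliquely.** Stage scanning sweeps a tilted
   image plane through the specimen; if the frame interval is chosen as
   *sampling · cos(tilt)* the resulting shear is exactly one pixel per image
   row and de-skewing reduces to integer row shifts — no interpolation.
   Strips tile laterally and vertically with overlap, are aligned by
   cross-correlation, blended, and optionally false-colored into
   pseudo-H&E via a Beer–Lambert absorption model.

otlskit implements both halves for people building or emulating such
instruments: the **design rules** (optics module), the **acquisition
geometry** (scan/tile planning, exponential depth power schedule
*P = P₀·exp(z/μ)*), a **phantom simulator** that renders ground-truth
volumes into raw oblique strips (Gaussian sheet weighting, depth
attenuation, camera noise, 16-bit quantization), and the full
**reconstruction pipeline** (de-skew → depth normalize → stitch → fuse →
colorize), plus TIFF/HDF5/CSV/XML containers and a CLI.

## Worked example

Holder design for ethyl-cinnamate (ECi) clearing at n = 1.56:

```text
$ otls design table --medium ECi
medium ECi (n=1.560, solvent)
material      class                   dn  t_max (mm)  chem
fused silica  glass               -0.100       0.020  ok
N-BK7         glass               -0.040       0.050  ok
PMMA          monomer_polymer     -0.070       0.029  ok
PS            monomer_polymer      0.030       0.067  INCOMPATIBLE
SMMA          monomer_polymer      0.000         inf  INCOMPATIBLE
SAN           monomer_polymer      0.010       0.200  INCOMPATIBLE
HIVEX         monomer_polymer     -0.010       0.200  ok
NK55          monomer_polymer      0.000         inf  ok
KOC55         monomer_polymer     -0.010       0.200  ok
FEP           fluoropolymer       -0.220       0.009  ok
PTFE          fluoropolymer       -0.210       0.010  ok
```

Each row gives the index mismatch Δn against the medium, the maximum
holder thickness `t_max = budget / |Δn|` that keeps the plate within the
0.002-mm OPD budget, and chemical compatibility (styrene-based polymers
are destroyed by organic solvents — which is why the resin monomers
HIVEX/NK55/KOC55 are the practical choice here despite SMMA's perfect
index match). The wavefront model behind the budget:

```text
$ otls design strehl --dn 0.001 --t 1.0
dn*t = 0.001000 mm
W_rms = 0.0512 waves
S = 0.9017
```

i.e. a 1-mm plate mismatched by 0.001 stays near-diffraction-limited
(S > 0.8), while `--dn 0.002` at the same thickness drops to S = 0.66.

The imaging constants at the solvent operating point:

```python
>>> import otlskit as ok
>>> train = ok.OpticalTrain()
>>> ok.sampling_um_per_px(train, 1.56)       # 6.5-um pixels / M(1.56)
0.43939393939393934
>>> ok.scan_interval_um(0.4394, 45.0)        # one-pixel-shear frame interval
0.31070347...
```

A full synthetic acquisition and reconstruction:

```sh
otls run --config examples/toy.yaml --seed 5 --out scratch/run
```

writes the tile plan, raw strips, stage metadata, tile-layout XML, fused
HDF5 volumes per channel and a pseudo-H&E slice, plus `manifest.json`
recording the config hash, seed, per-stage timings and warnings.

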