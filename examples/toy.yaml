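# Desk-scale synthetic acquisition: same optics and scan laws as the full
# instrument, but a 48 x 32 camera ROI and a ~20 x 40 x 10 um specimen so the
# whole pipeline runs in seconds.
schema_version: 1
optics:
  sensor_cols: 48
  roi_rows: 32
immersion:
  medium: ECi
extent_um: [20.0, 40.0, 10.0]
tiles:
  lateral_pitch_um: 15.0
  vertical_pitch_um: 6.0
simulator:
  n_nuclei: 20
  n_filaments: 4
  voxel_pitch_um: 0.6
  attenuation_um: 200.0
  read_sigma: 2.0
  photon_scale: 0.5
reconstruction:
  mu_um: 200.0
  max_shift_vox: 2
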