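# Counterflow-pair insonation described declaratively.
# Units are explicit in the field names and converted to SI on load.
scenario:
  name: counterflow_pair
grid:
  spacing_mm: 1.0
solver:
  dt_s: 0.1
source:
  p0_w_per_cm3: 15.0
  fwhm_width_mm: 4.0
  fwhm_height_mm: 30.0
  focus_mm: [30.0, 30.0, 20.0]
duration_s: 60.0
output: scratch/pair_run.npz
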