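# Geometry of the in-vitro single-detector platform: 41 sampling points at
# 1 mm pitch, 45 mm stand-off, 16.67 MHz sampling.  The measured data are
# not shipped; a synthetic ellipse stands in for the rectangular rubber
# absorber so the configuration runs end-to-end.
name: experimental_geometry
phantom: shepp_logan   # replace with a phantom YAML path to emulate the absorber
grid: {nx: 128, ny: 128, extent_mm: 50.0}
detector:
  line_length_mm: 40.0
  distance_mm: 45.0
  orientation: parallel-to-y
time:
  fs_hz: 1.667e+7
  duration_s: 5.0e-5
  c_mps: 1500.0
  max_bins: 512
sampling_points: [41]
solvers: [patch_tv, tv_gd, backprojection]
iterations: 10
params:
  default: {alpha: 0.55, beta: 0.45}
patch: {T: 0.60}
supersample: 2
seed: 0
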