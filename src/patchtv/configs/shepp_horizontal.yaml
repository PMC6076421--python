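# Shepp-Logan phantom, scanning line parallel to the minor axis
# (horizontal line below the image); same length and stand-off.
name: shepp_horizontal
phantom: shepp_logan
grid: {nx: 128, ny: 128, extent_mm: 76.8}
detector:
  line_length_mm: 76.0
  distance_mm: 38.0
  orientation: parallel-to-x
time:
  fs_hz: 2.0e+8
  c_mps: 1500.0
  max_bins: 512
sampling_points: [50, 20, 10]
solvers: [patch_tv, tv_gd, patch_re, backprojection]
iterations: 10
params:
  default: {alpha: 0.50, beta: 0.42}
patch: {T: 0.65}
supersample: 2
seed: 0
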