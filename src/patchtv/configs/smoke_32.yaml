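# Fast smoke test: 32x32 grid, single sampling count, all solvers.
name: smoke_32
phantom: shepp_logan
grid: {nx: 32, ny: 32, extent_mm: 76.8}
detector:
  line_length_mm: 76.0
  distance_mm: 38.0
  orientation: parallel-to-y
time:
  fs_hz: 2.0e+8
  c_mps: 1500.0
  max_bins: 128
sampling_points: [20]
solvers: [patch_tv, tv_gd, patch_re, backprojection]
iterations: 10
params:
  default: {alpha: 0.4, beta: 0.35}
patch: {T: 0.65, stride: 1, local_window: 7}
supersample: 2
seed: 0
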