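# patchtv

Iterative image reconstruction for **limited-view (straight-line scanned)
photoacoustic tomography**, combining a **nonlocal patch** prior with
**total-variation (TV)** regularization.

In photoacoustic imaging a laser pulse deposits energy in tissue according to
its optical absorption A(**r**); the resulting pressure transient is recorded
by ultrasound detectors. When the detectors lie on a single straight line —
the practical geometry of a linear array — a large angular range of
projections is missing and classical reconstructions show streaks, blur and
lost edges. `patchtv` implements a reconstruction model that supplements the
TV prior with the image's own self-similarity: each pixel's patch is pushed
toward a weighted average of similar patches found anywhere in the image.

## The model

With the detected signals integrated to arc data `g(r0, t) = ∮_{|r-r0|=ct} A ds`
and discretized to `g = M·A`, the reconstruction solves

```
A* = argmin_A  ‖M·A − g‖² + α·Σᵢ |Dᵢ A|₂ + β·‖(I − H)·A‖²
```

* `M` — sparse arc-quadrature projector (circle integrals by equal-angle
  sampling with bilinear pixel weights),
* `D` — discrete gradient; the middle term is isotropic TV,
* `H` — row-stochastic nonlocal operator: entry (i, j) is the normalized
  steering-kernel similarity weight `W_s(xᵢ, xⱼ)` of pixel j in the adaptive
  neighborhood δ(xᵢ) = {j : similarity > T}, searched over the whole image.
  The weights use a structure-tensor (direction-adaptive) distance, so
  neighborhoods elongate along edges.

The solver stacks `K = [M; √β(I−H)]`, splits `u = D·A`, and alternates a
closed-form shrinkage step for `u`, an FFT-diagonalized linear solve for `A`,
a Bregman-style update for the splitting variable `b`, and a
Barzilai–Borwein step-size update — 10 iterations by default. TV-only
(`tv_gd_reconstruct`, `tv_split_reconstruct`), patch-only
(`patch_re_reconstruct`) and backprojection baselines are included, plus
analytic Shepp–Logan and FORBILD-style head phantoms, a no-inverse-crime
signal simulator, Gaussian noise injection, and PSNR / relative-distance
metrics.

## Worked example

`python examples/04_patch_tv_reconstruction.py` reconstructs a 64×64
Shepp–Logan phantom from a 50-point scanning line (76 mm long, 38 mm from
the image center), 10 iterations, α = 0.4, β = 0.35, T = 0.65:

```
patch-TV       : PSNR  17.95 dB   d 0.551   (10 iterations)
Patch-RE       : PSNR  17.87 dB   d 0.555   (10 iterations)
TV-GD          : PSNR  17.41 dB   d 0.586   (10 iterations)
backprojection : PSNR  15.27 dB   d 0.749   (1 iterations)

patch-TV distance per iteration: 0.754 0.723 0.663 ... 0.566 0.551
```

PSNR (dB, against the un-normalized phantom; higher is better) and the
relative distance d (lower is better) rank the solvers: the combined
patch + TV model leads, the single-prior baselines follow, plain
backprojection trails. The d-per-iteration line decreases monotonically —
each pass of the splitting scheme refines the image. The other scripts in
`examples/` demonstrate the phantoms, the forward simulation, the structure
of `H`, and the noise-robustness study.

## Command line

```bash
patv run src/patchtv/configs/shepp_perpendicular.yaml --out runs/shepp
patv plot runs/shepp
patv reconstruct --config cfg.yaml --signals g.npy --out recon.npy --solver patch_tv
```

Each bundled YAML config describes one experiment of the simulation study
(phantom, grid, detector line, time sampling, solver parameters, sampling
point sweep, optional noise sweep); `patv run` writes reconstructed images
(`.npy` + display `.png`), a `metrics.csv` and a convergence chart,
deterministically for a fixed seed.

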