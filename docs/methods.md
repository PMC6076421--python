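# Methods

## Forward model

The imaging equation is the 2-D circular-mean relation: the time-integrated,
`t`-weighted pressure record of an ideal point detector at `r0` equals the
arc integral of the absorption image over the circle `|r − r0| = c·t`
(`g_from_pressure` provides the pressure-to-g chain with the physical
constants; the solvers consume `g` directly, where the constants cancel).

The discrete projector `M` maps a pixel image to `(detector, time-bin)`
samples. Each row integrates the bilinear interpolant of the image along its
arc: the circle is sampled at equal angles with at least `samples_per_pixel`
(default 4) points per crossed pixel, each sample carries its arc-length
element `r·Δθ` (mm), and deposits it on the four surrounding pixel centers
with bilinear weights. Samples outside the pixel-center bounding box are
**dropped**, not clamped: folding them onto border pixels gives the border
columns enormous spurious weight and visibly corrupts the spectrum of
`MᵀM` (a full-view control reconstruction fails with clamping and converges
to ~59 dB without it). The operator is exactly linear and its adjoint is the
transpose, which the tests verify to machine precision.

**Geometry.** Physical coordinates are millimetres, origin at the image
center, x rightward, y upward; pixel (0, 0) is the top-left center. The
scanning line is vertical at `x = +d` ("perpendicular" study, line parallel
to the phantom's major axis) or horizontal at `y = −d`. The speed of sound
defaults to 1500 m/s (soft tissue). A 20 µs window at that speed spans only
30 mm and cannot cover a 76.8 mm image scanned from 38 mm away, so
`TimeGrid.covering` starts the window at the nearest image point and extends
it to the farthest one, logging a warning when it overrides a configured
duration. At 200 MHz this yields ~14 000 samples per detector; the time axis
is decimated to at most `max_bins` (default 512 in the shipped configs —
0.2 mm radial spacing, three times finer than the 0.6 mm pixel) to bound the
size of `M`.

**No inverse crime.** Study signals are synthesized by an independent
projector built on a grid `supersample ≥ 2` times finer than the
reconstruction grid (itself rasterized with 2×2 sub-pixel averaging). The
gap between such data and the coarse operator converges not to zero but to
the coarse grid's representation error (≈4 % of signal energy at 128²,
≈8–11 % at 32²) — the price of honest data generation; the tests assert
boundedness and stabilization of this gap rather than decay.

## Nonlocal patch operator

Per pixel j, a structure tensor `G_j` (Gaussian-smoothed gradient outer
product, σ = 1.5 px) is eigen-decomposed and mapped to the unit-determinant
steering tensor `S_j = U diag(λ₁+ε, λ₂+ε; ratios) Uᵀ`, elongated along the
local edge; the density scalar is `μ_j = (λ₁λ₂ + ε²)^¼`, normalized by its
image mean so the typical μ is 1 and the bandwidth h (default 8) is in
pixels. The pairwise weight is

    W_s(xᵢ, xⱼ) = √det(S_j) / (2π h² μ_j²) · exp(−E_ij),
    E_ij = (xᵢ−xⱼ)ᵀ S_j (xᵢ−xⱼ) / (2 h² μ_j²)  +  MSD_ij / (2 (patch_h·σ_A)²),

where `MSD` is the Gaussian-windowed mean squared difference between the two
3×3 patches and `σ_A` the image standard deviation (`patch_h` default 0.4,
NLM convention). Decoupling the content term from μ matters: normalized by
`2h²μ²` it switches off exactly at edges (large μ), and the operator built
from the true phantom then fails to annihilate it (residual 61 % of image
norm vs. 2–5 % with the decoupled form).

Candidates for each pixel are the whole image subsampled at
`candidate_stride` (default 2) plus a local window (11×11). Screening uses
the exponential similarity `exp(−E_ij)` alone — exactly 1 at the pixel
itself, so the threshold T ∈ (0, 1) has a fixed meaning, raising T can only
shrink neighborhoods, and T → 1 degenerates H to the identity. Kept weights
(the largest `max_neighbors` = 24 above T, self always included) carry the
full prefactor and are renormalized to sum exactly 1: H is row-stochastic,
constants are exact fixed points, and the patch penalty `β‖(I−H)A‖²`
vanishes on flat images. Pairwise weights are evaluated in float32 (they
only feed a ranking, a screen and a renormalized convex combination); the
final rows are renormalized in float64.

Inside the solver H is rebuilt from the current iterate every
`rebuild_every` iterations (default 1), max-normalized so the bandwidth sees
a consistent intensity scale; before the first iterate exists it is built
from the normalized backprojection `Mᵀg`, since the all-zero initial image
has no structure.

## Solver

The stacked operator `K = [M; √β(I−H)]` realizes the objective
`‖MA−g‖² + βΣ‖(I−H)A‖²` exactly (stacking β instead of √β would square the
patch weight). The iteration alternates:

1. **u-step** — per-pixel exact minimizer of
   `|u| + |u − (DAⁿ + bⁿ)|² + (σ/α)|u − uⁿ|²`: soft-thresholding of
   `v = 2a₁ + 2(σ/α)a₂` at radius 1 with contraction `2(1+σ/α)`, validated
   against a derivative-free 2-D minimizer on 200 random tuples.
2. **A-step** — the exact solve of `(αDᵀD + σI)A = αDᵀu + σAⁿ − Kᵀ(KAⁿ−g̃)`
   by pointwise division over the 2-D DFT. Forward differences with periodic
   wrap are used throughout (required for the Fourier diagonalization); the
   seam contributes to the penalty but the phantoms are zero at the border.
3. **b-step and step size** — `b ← b − (u − DA)`;
   `σ ← |KΔA|² / (|Δu|² + |ΔA|²)`, floored at 0.1× the running Rayleigh
   estimate of λmax(KᵀK). Without the floor the ratio can fall far below
   the stability bound of the quadratic term once the patch rows enter K
   (divergence observed for β ≳ 1); 0.1 preserves the acceleration while
   keeping a safety net.
4. **stop** — relative u-change below ε (default 1e-6), checked from the
   second iteration on: the initialization A⁰ = 0, b⁰ = 0 keeps u ≡ 0
   through the shrinkage dead zone, where the criterion is vacuous.

**Calibrations the model leaves open, fixed once here.** `M` is normalized
to unit spectral norm (power iteration, deterministic start) with `g` scaled
identically, so the data term is commensurate with the regularizers at the
published parameter magnitudes. The shrinkage threshold is an absolute
constant, so the iteration's behavior depends on the image gray scale; the
solvers therefore iterate on an 8-bit-style scale (`gray_scale` = 255,
output mapped back), consistent with computing PSNR on "un-normalized"
images. On a [0, 1] scale the threshold crushes all gradients regardless of
α.

**Baselines.** `tv_gd_reconstruct` is plain gradient descent on the
ε-smoothed TV objective with a backtracked (monotone) step — an approximate
stand-in whose internals are this package's own choices.
`patch_re_reconstruct` is Barzilai–Borwein descent on the data + patch
objective without TV or splitting. `backprojection` is `Mᵀg` with a
least-squares scalar fit.

## Phantoms and metrics

The Shepp–Logan phantom is the standard 10-ellipse table with modified
(Toft) intensities, scaled to 76.8 mm, cross-checked against an independent
raster in the tests. The FORBILD-style head is an ellipse-only synthetic
stand-in (10 ellipses: bright skull shell at 1.8, brain at 1.05, air cavity,
eyes, ventricles, small lesions) — the published FORBILD definition mixes
ellipses with other primitives and no exact pixel-level match is claimed.
Overlapping intensities add. Rasterization averages `supersample²` analytic
sub-samples per pixel and is linear in the intensities.

PSNR uses `10·log₁₀(NxNy·MAXI²/SSE)` with MAXI the peak of the
un-normalized reference (1.0 for Shepp–Logan, 1.8 for the head phantom);
`d = (SSE/ΣR²)^½`. Display normalization (divide by max) is never applied
before metrics.

## What the synthetic study shows — and its limits

The generator reproduces the study conditions: 76.8 mm phantoms, a 76 mm
line at 38 mm, 50/20/10 sampling points, 200 MHz sampling, 10 iterations,
and the published (α, β, T) per experiment. It does not emulate transducer
bandwidth or aperture, acoustic attenuation or heterogeneity, or 3-D
spherical spreading, so passing tests speak to the algorithmic claims, not
to hardware realism.

Two regimes should be distinguished when reading the numbers. The
*qualitative* structure of the published study reproduces deterministically:
patch-TV > Patch-RE > TV-GD > backprojection in every noiseless
configuration, PSNR non-increasing as sampling drops 50→20→10, patch-TV
ahead at every noise level, and the smallest final distance on the sparsest
head-phantom case. The *absolute* PSNR magnitudes do not: at this geometry
the limited-view spectrum makes the data term extremely ill-conditioned
(clean-data LSQR needs ~800 Krylov iterations for 26 dB at 64²), and deep
solves of the TV objective over a wide α range cap near 20 dB, so
first-order iterations of this family reach ≈17 dB at 10 iterations rather
than the published 23–35 dB. The acceptance script reports the measured
values as computed; nothing is fitted to the published tables.

Other known limitations: the patch prior's gain over TV is small on the
piecewise-constant phantoms (fractions of a dB — its margin is systematic
but thin); H rebuilt from an artifact-laden early iterate can only encode
the structure that iterate contains; and the periodic-boundary TV seam would
bias images that are nonzero at the border.
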