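"""Patch-TV reconstruction by variable splitting with Barzilai--Borwein steps,
plus TV-gradient-descent and patch-only baselines and plain backprojection.

The patch-TV objective over the image A (flattened row-major) is

    min_A ||M A - g||_2^2 + alpha * sum_i |u_i|_2 + beta * ||(I - H) A||_2^2,
    u_i = D_i A,

with M the arc projector, D the forward-difference gradient (periodic
boundary, so D^T D diagonalizes under the 2-D DFT), and H the row-stochastic
nonlocal patch operator.  Stacking K = [M; sqrt(beta) (I - H)] and
g~ = [g; 0] turns the data and patch terms into a single quadratic, and the
splitting alternates:

  u-step   : per-pixel shrinkage (exact closed form),
  A-step   : one FFT-diagonalized linear solve
             (alpha D^T D + sigma_n I) A = alpha D^T u + sigma_n A^n - K^T(K A^n - g~),
  b-step   : b^{n+1} = b^n - (u^{n+1} - D A^{n+1}),
  sigma    : sigma_{n+1} = |K dA|^2 / (|du|^2 + |dA|^2)  (Barzilai--Borwein),

stopping when ||u^n - u^{n-1}|| / ||u^n|| < epsilon or after max_iters.

M is rescaled to unit spectral norm (g scaled identically) before solving so
the data-fidelity term is commensurate with the regularizers at the
published parameter magnitudes; the solution is unaffected by a consistent
rescaling of an unregularized problem and only the meaning of (alpha, beta)
depends on it, which is fixed once here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .forward import ProjectionMatrix, SignalSet
from .patches import PatchConfig, build_nonlocal_operator
from .phantoms import ImageGrid

__all__ = [
    "SolverParams",
    "SolverState",
    "StackedOperator",
    "ReconResult",
    "tv_value",
    "shrink_step",
    "image_update",
    "bb_step_update",
    "stopping_check",
    "patch_tv_reconstruct",
    "tv_split_reconstruct",
    "tv_gd_reconstruct",
    "patch_re_reconstruct",
    "backprojection",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverParams:
    """Weights and loop controls of the splitting solver.

    alpha: TV weight; beta: nonlocal-patch weight; max_iters: outer
    iterations (10 reproduces the study conditions); epsilon: relative
    u-change stopping tolerance; sigma0: initial step scalar; gray_scale:
    intensity scale the iteration runs on (the shrinkage threshold is an
    absolute constant, so the algorithm is defined on 8-bit-style gray
    levels: a unit-intensity phantom iterates at gray_scale and is mapped
    back on output).
    """

    alpha: float = 0.4
    beta: float = 0.35
    max_iters: int = 10
    epsilon: float = 1e-6
    sigma0: float = 1.0
    gray_scale: float = 255.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass
class SolverState:
    """Per-iteration variables of the splitting scheme."""

    A: np.ndarray          # current image (ny, nx)
    u: np.ndarray          # (2, ny, nx) gradient surrogate
    b: np.ndarray          # (2, ny, nx) Bregman/step parameter
    sigma: float
    iteration: int = 0


@dataclass
class ReconResult:
    image: ImageGrid
    d_per_iter: list = field(default_factory=list)
    objective_per_iter: list = field(default_factory=list)
    iters_run: int = 0
    converged: bool = False
    solver: str = ""


# ---------------------------------------------------------------------------
# finite differences (forward, periodic) and TV


def grad_forward(A: np.ndarray) -> np.ndarray:
    """Forward differences with periodic wrap: out[0] along rows (y),
    out[1] along columns (x); shape (2, ny, nx)."""
    return np.stack([np.roll(A, -1, axis=0) - A, np.roll(A, -1, axis=1) - A])


def div_adjoint(u: np.ndarray) -> np.ndarray:
    """Adjoint D^T of grad_forward: <D A, u> = <A, D^T u> exactly."""
    return (np.roll(u[0], 1, axis=0) - u[0]) + (np.roll(u[1], 1, axis=1) - u[1])


def tv_value(A, boundary: str = "zero") -> float:
    """Isotropic total variation sum_{m,n} sqrt(dy^2 + dx^2) with backward
    differences; ``boundary`` "zero" drops differences across the image
    border, "periodic" wraps them."""
    v = A.values if isinstance(A, ImageGrid) else np.asarray(A, dtype=float)
    if boundary == "periodic":
        dy = v - np.roll(v, 1, axis=0)
        dx = v - np.roll(v, 1, axis=1)
    elif boundary == "zero":
        dy = np.zeros_like(v)
        dx = np.zeros_like(v)
        dy[1:, :] = v[1:, :] - v[:-1, :]
        dx[:, 1:] = v[:, 1:] - v[:, :-1]
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")
    return float(np.sqrt(dy**2 + dx**2).sum())


# ---------------------------------------------------------------------------
# stacked operator


class StackedOperator:
    """K = [M ; sqrt(beta) (I - H)] acting on flattened images, with
    g~ = [g ; 0]; the patch block is absent when beta = 0 or H is None."""

    def __init__(self, M: sp.csr_array, g: np.ndarray, beta: float,
                 H: sp.csr_array | None):
        self.M = M
        self.gflat = np.asarray(g, dtype=float).ravel()
        self.beta = float(beta)
        if beta > 0 and H is not None:
            n = H.shape[0]
            self.B = sp.csr_array(sp.eye_array(n, format="csr") - H)
            self.sb = np.sqrt(beta)
        else:
            self.B = None
            self.sb = 0.0

    def apply(self, Aflat: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        r1 = self.M @ Aflat
        r2 = self.sb * (self.B @ Aflat) if self.B is not None else None
        return r1, r2

    def gradient(self, Aflat: np.ndarray) -> np.ndarray:
        """K^T (K A - g~)."""
        r1, r2 = self.apply(Aflat)
        out = self.M.T @ (r1 - self.gflat)
        if r2 is not None:
            out = out + self.sb * (self.B.T @ r2)
        return out

    def residual_sq(self, Aflat: np.ndarray) -> float:
        r1, r2 = self.apply(Aflat)
        val = float(((r1 - self.gflat) ** 2).sum())
        if r2 is not None:
            val += float((r2**2).sum())
        return val

    def apply_diff_norm_sq(self, dAflat: np.ndarray) -> float:
        """|K dA|_2^2 (numerator of the Barzilai--Borwein update)."""
        r1, r2 = self.apply(dAflat)
        val = float((r1**2).sum())
        if r2 is not None:
            val += float((r2**2).sum())
        return val


# ---------------------------------------------------------------------------
# elementary steps


def shrink_step(a1: np.ndarray, a2: np.ndarray, alpha: float, sigma_n: float) -> np.ndarray:
    """Exact minimizer, per pixel, of |u|_2 + |u - a1|_2^2 + (sigma/alpha)|u - a2|_2^2.

    With t = sigma/alpha, c = 2(1 + t) and v = 2 a1 + 2 t a2 the solution is
    u = max(|v| - 1, 0)/c * v/|v| (and u = 0 when v = 0): soft-thresholding
    of the combined pull toward a1 and a2.
    """
    if not (alpha > 0 and sigma_n > 0):
        raise ValueError("alpha and sigma_n must be positive")
    t = sigma_n / alpha
    c = 2.0 * (1.0 + t)
    v = 2.0 * a1 + 2.0 * t * a2
    mag = np.sqrt((v**2).sum(axis=0))
    scale = np.maximum(mag - 1.0, 0.0) / c
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, v / mag, 0.0)
    return scale * unit


def _laplacian_symbol(ny: int, nx: int) -> np.ndarray:
    """Eigenvalues of D^T D (periodic forward differences) on the DFT grid."""
    wy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(ny) / ny)
    wx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(nx) / nx)
    return wy[:, None] + wx[None, :]


def image_update(
    A_n: np.ndarray,
    u_next: np.ndarray,
    grad_data: np.ndarray,
    alpha: float,
    sigma_n: float,
) -> np.ndarray:
    """Exact solve of (alpha D^T D + sigma_n I) A = rhs with
    rhs = alpha D^T u_next + sigma_n A_n - grad_data, by pointwise division
    over the 2-D DFT (grad_data = K^T (K A^n - g~) reshaped to the image)."""
    if not sigma_n > 0:
        raise ValueError("sigma_n must be positive")
    ny, nx = A_n.shape
    rhs = sigma_n * A_n - grad_data
    if alpha > 0:
        rhs = rhs + alpha * div_adjoint(u_next)
    denom = alpha * _laplacian_symbol(ny, nx) + sigma_n
    return np.real(np.fft.ifft2(np.fft.fft2(rhs) / denom))


def bb_step_update(
    K: StackedOperator,
    A_n: np.ndarray,
    A_next: np.ndarray,
    u_n: np.ndarray,
    u_next: np.ndarray,
    b_n: np.ndarray,
    sigma_n: float,
    sigma_floor: float = 0.0,
) -> tuple[np.ndarray, float]:
    """b^{n+1} = b^n - (u^{n+1} - D A^{n+1});
    sigma_{n+1} = |K dA|^2 / (|du|^2 + |dA|^2), kept at sigma_n when the
    denominator vanishes (no change between iterates).

    ``sigma_floor`` optionally bounds sigma from below; the solvers pass
    half the running Rayleigh estimate of lambda_max(K^T K), which keeps
    the implied gradient step 1/sigma inside the stability region of the
    quadratic term (the raw ratio can otherwise drop far below it once the
    stacked operator carries the patch rows).
    """
    b_next = b_n - (u_next - grad_forward(A_next))
    dA = (A_next - A_n).ravel()
    du = u_next - u_n
    denom = float((du**2).sum() + (dA**2).sum())
    if denom == 0.0:
        return b_next, sigma_n
    num = K.apply_diff_norm_sq(dA)
    sigma_next = max(num / denom, sigma_floor)
    if not np.isfinite(sigma_next) or sigma_next <= 0:
        sigma_next = sigma_n
    return b_next, sigma_next


def stopping_check(u_n: np.ndarray, u_prev: np.ndarray, epsilon: float) -> bool:
    """||u^n - u^{n-1}|| / ||u^n|| < epsilon; both norms zero counts as
    converged, a zero current norm with nonzero change does not."""
    nn = float(np.linalg.norm(u_n.ravel()))
    nd = float(np.linalg.norm((u_n - u_prev).ravel()))
    if nn == 0.0:
        return nd == 0.0
    return nd / nn < epsilon


# ---------------------------------------------------------------------------
# full solvers


def _to_grid(values: np.ndarray, M: ProjectionMatrix) -> ImageGrid:
    return ImageGrid(values=values, pixel_size=M.pixel_size, origin=M.origin)


def _distance(A: np.ndarray, R: np.ndarray) -> float:
    return float(np.sqrt(((A - R) ** 2).sum() / (R**2).sum()))


def _normalized(M: ProjectionMatrix, g: SignalSet) -> tuple[sp.csr_array, np.ndarray]:
    s = M.spectral_norm
    if s == 0:
        raise ValueError("projection matrix is zero")
    return sp.csr_array(M.matrix / s), g.values.ravel() / s


def _check_shapes(g: SignalSet, M: ProjectionMatrix) -> None:
    n_rows = g.det.n_points * g.tg.n_samples
    if M.matrix.shape[0] != n_rows:
        raise ValueError(
            f"signals ({n_rows} samples) inconsistent with projector rows "
            f"({M.matrix.shape[0]})"
        )


def _h_image(A: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Image the patch weights are computed from: the current iterate, or a
    normalized backprojection before any iterate exists; max-normalized so
    the weight bandwidth sees a consistent intensity scale."""
    src = A if np.abs(A).max() > 0 else fallback
    peak = np.abs(src).max()
    return src / peak if peak > 0 else src


def patch_tv_reconstruct(
    g: SignalSet,
    M: ProjectionMatrix,
    params: SolverParams,
    patch_cfg: PatchConfig | None = None,
    reference: np.ndarray | None = None,
) -> ReconResult:
    """Patch-TV splitting solver (the combined nonlocal-patch + TV model).

    ``reference``: optional ground-truth image; when given, the relative
    distance d is recorded each iteration.  H is rebuilt from the current
    iterate every ``patch_cfg.rebuild_every`` iterations (from a normalized
    backprojection at iteration 0, where A^0 = 0 has no structure).
    """
    _check_shapes(g, M)
    if patch_cfg is None:
        patch_cfg = PatchConfig()
    ny, nx = M.grid_shape
    Mn, gn = _normalized(M, g)
    gs = params.gray_scale
    gn = gn * gs
    bp = (Mn.T @ gn).reshape(ny, nx)

    state = SolverState(
        A=np.zeros((ny, nx)),
        u=np.zeros((2, ny, nx)),
        b=np.zeros((2, ny, nx)),
        sigma=params.sigma0,
    )
    use_patch = params.beta > 0
    H = None
    result = ReconResult(image=_to_grid(state.A, M), solver="patch_tv")
    alpha = params.alpha
    lam_est = 0.0  # running Rayleigh estimate of lambda_max(K^T K)

    for n in range(params.max_iters):
        if use_patch and (H is None or n % patch_cfg.rebuild_every == 0):
            H = build_nonlocal_operator(_h_image(state.A, bp), patch_cfg).H
        K = StackedOperator(Mn, gn, params.beta, H)
        if alpha > 0:
            a1 = grad_forward(state.A) + state.b
            u_next = shrink_step(a1, state.u, alpha, state.sigma)
        else:
            u_next = state.u
        grad_data = K.gradient(state.A.ravel()).reshape(ny, nx)
        A_next = image_update(state.A, u_next, grad_data, alpha, state.sigma)
        if not np.all(np.isfinite(A_next)):
            raise RuntimeError(
                f"non-finite iterate at iteration {n + 1} "
                f"(sigma={state.sigma:.3g}); check operator scaling"
            )
        dA = (A_next - state.A).ravel()
        ndA = float(dA @ dA)
        if ndA > 0:
            lam_est = max(lam_est, K.apply_diff_norm_sq(dA) / ndA)
        b_next, sigma_next = bb_step_update(
            K, state.A, A_next, state.u, u_next, state.b, state.sigma,
            sigma_floor=0.1 * lam_est,
        )
        obj = K.residual_sq(A_next.ravel()) + alpha * float(
            np.sqrt((grad_forward(A_next) ** 2).sum(axis=0)).sum()
        )
        result.objective_per_iter.append(obj)
        if reference is not None:
            result.d_per_iter.append(_distance(A_next / gs, reference))
        # the u field is identically zero for the first iterations (shrink
        # dead zone from A^0 = 0); the relative-change stop is meaningful
        # only once u has left it
        converged = (
            n >= 2
            and float(np.abs(u_next).max()) > 0.0
            and stopping_check(u_next, state.u, params.epsilon)
        )
        state = SolverState(A=A_next, u=u_next, b=b_next, sigma=sigma_next,
                            iteration=n + 1)
        result.iters_run = n + 1
        log.debug("iter %d: obj=%.6g sigma=%.3g", n + 1, obj, sigma_next)
        if converged:
            result.converged = True
            break

    result.image = _to_grid(state.A / gs, M)
    return result


def tv_split_reconstruct(
    g: SignalSet,
    M: ProjectionMatrix,
    params: SolverParams,
    reference: np.ndarray | None = None,
) -> ReconResult:
    """TV-only splitting solver: the identical engine with the patch block
    removed (beta = 0)."""
    from dataclasses import replace

    res = patch_tv_reconstruct(g, M, replace(params, beta=0.0), None, reference)
    res.solver = "tv_split"
    return res


def backprojection(g: SignalSet, M: ProjectionMatrix) -> ReconResult:
    """Adjoint surface M^T g with a least-squares scalar fit (baseline)."""
    _check_shapes(g, M)
    bp = M.adjoint(g.values)
    mg = M.apply(bp).ravel()
    denom = float((mg**2).sum())
    scale = float(mg @ g.values.ravel()) / denom if denom > 0 else 0.0
    return ReconResult(image=_to_grid(scale * bp, M), iters_run=1,
                       solver="backprojection")


def _smooth_tv_grad(A: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """epsilon-smoothed isotropic TV (periodic forward differences) and its
    gradient."""
    u = grad_forward(A)
    mag = np.sqrt((u**2).sum(axis=0) + eps)
    val = float(mag.sum())
    grad = div_adjoint(u / mag)
    return val, grad


def tv_gd_reconstruct(
    g: SignalSet,
    M: ProjectionMatrix,
    params: SolverParams,
    reference: np.ndarray | None = None,
    tv_eps: float = 1e-8,
) -> ReconResult:
    """TV-GD baseline: gradient descent on ||M A - g||^2 + alpha*TV_eps(A)
    with backtracked step (halved until the objective decreases).  An
    approximate stand-in for gradient-descent TV reconstruction; internals
    are this package's own choices.
    """
    _check_shapes(g, M)
    ny, nx = M.grid_shape
    Mn, gn = _normalized(M, g)
    gs = params.gray_scale
    gn = gn * gs
    A = np.zeros((ny, nx))
    result = ReconResult(image=_to_grid(A, M), solver="tv_gd")

    def objective(x):
        r = Mn @ x.ravel() - gn
        tv, _ = _smooth_tv_grad(x, tv_eps)
        return float((r**2).sum()) + params.alpha * tv

    obj = objective(A)
    bp = (Mn.T @ gn).reshape(ny, nx)
    step = None
    for n in range(params.max_iters):
        r = Mn @ A.ravel() - gn
        _, tvg = _smooth_tv_grad(A, tv_eps)
        grad = 2.0 * (Mn.T @ r).reshape(ny, nx) + params.alpha * tvg
        gmax = np.abs(grad).max()
        if gmax == 0:
            result.converged = True
            break
        if step is None:
            step = 0.5 * np.abs(bp).max() / gmax
        # backtracking: keep the objective monotone
        for _ in range(40):
            A_try = A - step * grad
            obj_try = objective(A_try)
            if obj_try <= obj:
                break
            step *= 0.5
        A, obj = A_try, obj_try
        step *= 1.2  # gentle growth so backtracking stays active
        result.objective_per_iter.append(obj)
        if reference is not None:
            result.d_per_iter.append(_distance(A / gs, reference))
        result.iters_run = n + 1
    result.image = _to_grid(A / gs, M)
    return result


def patch_re_reconstruct(
    g: SignalSet,
    M: ProjectionMatrix,
    params: SolverParams,
    patch_cfg: PatchConfig | None = None,
    reference: np.ndarray | None = None,
) -> ReconResult:
    """Patch-RE baseline: Barzilai--Borwein gradient descent on
    ||M A - g||^2 + beta ||(I - H) A||^2 (no TV term, no splitting)."""
    _check_shapes(g, M)
    if patch_cfg is None:
        patch_cfg = PatchConfig()
    ny, nx = M.grid_shape
    Mn, gn = _normalized(M, g)
    gs = params.gray_scale
    gn = gn * gs
    bp = (Mn.T @ gn).reshape(ny, nx)
    A = np.zeros((ny, nx))
    result = ReconResult(image=_to_grid(A, M), solver="patch_re")
    H = None
    grad_prev = None
    A_prev = None
    for n in range(params.max_iters):
        if params.beta > 0 and (H is None or n % patch_cfg.rebuild_every == 0):
            H = build_nonlocal_operator(_h_image(A, bp), patch_cfg).H
        K = StackedOperator(Mn, gn, params.beta, H)
        grad = 2.0 * K.gradient(A.ravel()).reshape(ny, nx)
        gmax = np.abs(grad).max()
        if gmax == 0:
            result.converged = True
            break
        if grad_prev is None:
            step = 0.5 * np.abs(bp).max() / gmax
        else:
            s = (A - A_prev).ravel()
            y = (grad - grad_prev).ravel()
            sy = float(s @ y)
            yy = float(y @ y)
            step = sy / yy if (yy > 0 and sy > 0) else step  # noqa: F821
        A_prev, grad_prev = A, grad
        A = A - step * grad
        if not np.all(np.isfinite(A)):
            raise RuntimeError(f"non-finite iterate at iteration {n + 1}")
        obj = K.residual_sq(A.ravel())
        result.objective_per_iter.append(obj)
        if reference is not None:
            result.d_per_iter.append(_distance(A / gs, reference))
        result.iters_run = n + 1
    result.image = _to_grid(A / gs, M)
    return result
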