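"""Direction-adaptive nonlocal patch weights and the sparse operator H.

Each pixel's patch is estimated as a convex combination of similar patches
screened over the whole image.  Similarity uses a steering-kernel weight

    W_s(x_i, x_j) = sqrt(det S_j) / (2 pi h^2 mu_j^2)
                    * exp(- Q(x_i, x_j) / (2 h^2 mu_j^2)),

where S_j is a unit-determinant structure tensor at the candidate pixel j
(elongated along the local edge direction, so equal-weight contours are
ellipses following structure), mu_j is a local density scalar derived from
the gradient-energy eigenvalues, and Q is the anisotropic squared distance
optionally augmented by the (Gaussian-windowed, variance-normalized) mean
squared difference between the two patches.  Per row, weights are
max-normalized to [0, 1], screened by the threshold T, capped at the
``max_neighbors`` largest, and renormalized to sum exactly 1 (the pixel
itself is always kept), giving a row-stochastic sparse matrix H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .phantoms import ImageGrid

__all__ = [
    "PatchConfig",
    "StructureTensorField",
    "NonlocalOperator",
    "compute_structure_tensors",
    "patch_weight",
    "build_nonlocal_operator",
]


@dataclass(frozen=True)
class PatchConfig:
    """Tunables of the nonlocal weight construction.

    patch_radius: patches are (2r+1)^2 pixels.
    h: global smoothing bandwidth in pixels (typical weight reach).
    T: similarity threshold in (0, 1) applied to max-normalized weights.
    tensor_smoothing: Gaussian sigma (pixels) for the structure tensor.
    max_neighbors: cap on neighborhood size per pixel.
    candidate_stride: whole-image candidate subsampling stride.
    local_window: side of the always-searched local window (odd).
    rebuild_every: solver-side schedule for recomputing H.
    include_patch_term: add patch-content dissimilarity to the distance.
    """

    patch_radius: int = 1
    h: float = 8.0
    T: float = 0.65
    tensor_smoothing: float = 1.5
    max_neighbors: int = 24
    candidate_stride: int = 2
    local_window: int = 11
    rebuild_every: int = 1
    include_patch_term: bool = True
    patch_h: float = 0.4

    def __post_init__(self):
        if not (0.0 < self.T < 1.0):
            raise ValueError("T must lie in (0, 1)")
        if not self.h > 0:
            raise ValueError("h must be positive")
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if self.candidate_stride < 1:
            raise ValueError("candidate_stride must be >= 1")
        if self.local_window < 1 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 1")


@dataclass
class StructureTensorField:
    """Per-pixel symmetric 2x2 tensors (S11, S12, S22), density mu and the
    raw gradient-energy eigenvalues (lam1 >= lam2 >= 0); all (ny, nx)."""

    S11: np.ndarray
    S12: np.ndarray
    S22: np.ndarray
    mu: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.S11.shape


def _as_values(A) -> np.ndarray:
    if isinstance(A, ImageGrid):
        return A.values
    return np.asarray(A, dtype=float)


def compute_structure_tensors(A, cfg: PatchConfig) -> StructureTensorField:
    """Steering-kernel structure tensors of the image.

    G_j = Gaussian-window smoothing of the gradient outer product; with
    eigenpairs (lam1, e1), (lam2, e2) of G_j the unit-determinant tensor is

        S_j = e1 e1^T * (lam1+eps)/(lam2+eps) + e2 e2^T * (lam2+eps)/(lam1+eps)

    (eps regularizes flat regions, where S_j falls back to the identity),
    and mu_j = (lam1*lam2 + eps^2)^(1/4) normalized by its image mean so the
    typical density is 1 and h acts as a bandwidth in pixels.
    """
    v = _as_values(A)
    if not np.all(np.isfinite(v)):
        raise ValueError("image must be finite")
    gy, gx = np.gradient(v)
    sig = cfg.tensor_smoothing
    G11 = gaussian_filter(gx * gx, sig)
    G12 = gaussian_filter(gx * gy, sig)
    G22 = gaussian_filter(gy * gy, sig)
    tr = G11 + G22
    disc = np.sqrt(np.maximum((G11 - G22) ** 2 + 4.0 * G12**2, 0.0))
    lam1 = np.maximum((tr + disc) / 2.0, 0.0)
    lam2 = np.maximum((tr - disc) / 2.0, 0.0)
    eps = 1e-3 * lam1 + 1e-12 + 1e-9 * float(lam1.max())
    d1 = (lam1 + eps) / (lam2 + eps)  # >= 1; det(S) = d1 * (1/d1) = 1
    d2 = 1.0 / d1
    # unit eigenvector for lam1: (G12, lam1 - G11), falling back to (1, 0)
    ex = G12.copy()
    ey = lam1 - G11
    nrm = np.hypot(ex, ey)
    degenerate = nrm < 1e-30
    ex = np.where(degenerate, 1.0, ex)
    ey = np.where(degenerate, 0.0, ey)
    nrm = np.where(degenerate, 1.0, nrm)
    ex /= nrm
    ey /= nrm
    S11 = d1 * ex * ex + d2 * ey * ey
    S12 = (d1 - d2) * ex * ey
    S22 = d1 * ey * ey + d2 * ex * ex
    mu_raw = (lam1 * lam2 + eps**2) ** 0.25
    mu = mu_raw / float(mu_raw.mean())
    return StructureTensorField(S11=S11, S12=S12, S22=S22, mu=mu, lam1=lam1, lam2=lam2)


def patch_weight(i: int, j: int, tensors: StructureTensorField, cfg: PatchConfig) -> float:
    """Raw steering-kernel weight between pixel centers i and j (flat
    row-major indices): center-displacement quadratic form only."""
    ny, nx = tensors.shape
    iy, ix = divmod(int(i), nx)
    jy, jx = divmod(int(j), nx)
    if not (0 <= iy < ny and 0 <= jy < ny and 0 <= ix < nx and 0 <= jx < nx):
        raise IndexError("pixel index out of range")
    # displacement in pixel coordinates (dx along +x / columns, dy rows)
    dx = float(ix - jx)
    dy = float(iy - jy)
    S11, S12, S22 = tensors.S11[jy, jx], tensors.S12[jy, jx], tensors.S22[jy, jx]
    mu = tensors.mu[jy, jx]
    detS = S11 * S22 - S12**2
    q = S11 * dx * dx + 2.0 * S12 * dx * dy + S22 * dy * dy
    denom = 2.0 * cfg.h**2 * mu**2
    return float(np.sqrt(max(detS, 0.0)) / (np.pi * denom) * np.exp(-q / denom))


@dataclass
class NonlocalOperator:
    """Row-stochastic sparse pixel-to-pixel weight matrix H."""

    H: sp.csr_array
    shape: tuple[int, int]  # image (ny, nx)
    cfg: PatchConfig

    def apply(self, image: np.ndarray) -> np.ndarray:
        flat = np.asarray(image, dtype=float).ravel()
        out = self.H @ flat
        return out.reshape(self.shape) if np.asarray(image).ndim == 2 else out

    def save_coo_text(self, path) -> None:
        """Coordinate-format text export: 'row col weight' per line."""
        coo = self.H.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# H {self.H.shape[0]} x {self.H.shape[1]}\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r} {c} {v:.12g}\n")


def _extract_patches(v: np.ndarray, radius: int) -> np.ndarray:
    """(npix, (2r+1)^2) array of patches (reflect padding at borders)."""
    from numpy.lib.stride_tricks import sliding_window_view

    p = 2 * radius + 1
    padded = np.pad(v, radius, mode="reflect")
    win = sliding_window_view(padded, (p, p))
    return win.reshape(v.size, p * p)


def build_nonlocal_operator(A, cfg: PatchConfig) -> NonlocalOperator:
    """Assemble H from the image: whole-image candidate search at
    ``candidate_stride`` spacing plus a local window, steering-kernel
    weights, max-normalization, T-screening, top-``max_neighbors`` cap,
    exact row renormalization (self always kept)."""
    v = _as_values(A)
    ny, nx = v.shape
    npix = ny * nx
    tensors = compute_structure_tensors(v, cfg)
    S11f = tensors.S11.ravel()
    S12f = tensors.S12.ravel()
    S22f = tensors.S22.ravel()
    muf = tensors.mu.ravel()
    denomf = 2.0 * cfg.h**2 * muf**2  # per-candidate
    # det(S) = 1 by construction: prefactor = 1 / (pi * denom)
    pref = 1.0 / (np.pi * denomf)

    use_patch = cfg.include_patch_term
    if use_patch:
        P = _extract_patches(v, cfg.patch_radius)
        p = 2 * cfg.patch_radius + 1
        oy, ox = np.mgrid[-cfg.patch_radius : cfg.patch_radius + 1,
                          -cfg.patch_radius : cfg.patch_radius + 1]
        w_off = np.exp(-(ox**2 + oy**2) / (2.0 * max(cfg.patch_radius, 1) ** 2)).ravel()
        w_off /= w_off.sum()
        var = float(v.var())
        if var > 0:
            Pw = P * np.sqrt(w_off)
            p_sq = (Pw**2).sum(axis=1)
            # NLM-style content bandwidth: patch differences are compared
            # to (patch_h * image std)^2, independent of the spatial kernel
            patch_scale = 1.0 / (2.0 * cfg.patch_h**2 * var)
        else:
            use_patch = False

    # global candidate set: stride grid
    gy = np.arange(0, ny, cfg.candidate_stride)
    gx = np.arange(0, nx, cfg.candidate_stride)
    Gy, Gx = np.meshgrid(gy, gx, indexing="ij")
    global_idx = (Gy * nx + Gx).ravel()

    halfw = cfg.local_window // 2
    K = cfg.max_neighbors

    rows_out, cols_out, data_out = [], [], []
    nc_est = global_idx.size + (2 * halfw + 1) * nx
    band = max(1, int(2e6 // max(nx * nc_est, 1)))
    for r0 in range(0, ny, band):
        r1 = min(r0 + band, ny)
        I = np.arange(r0 * nx, r1 * nx)  # row pixels (flat, raster order)
        lo = max(0, r0 - halfw)
        hi = min(ny, r1 + halfw)
        local_idx = np.arange(lo * nx, hi * nx)
        C = np.union1d(global_idx, local_idx)
        # pairwise kernel in float32: the weights feed a ranking, a T-screen
        # and a renormalized convex combination, none of which need more
        # than single precision (rows are exactly renormalized at the end)
        iy = (I[:, None] // nx).astype(np.float32)
        ix = (I[:, None] % nx).astype(np.float32)
        jy = (C[None, :] // nx).astype(np.float32)
        jx = (C[None, :] % nx).astype(np.float32)
        dx = ix - jx
        dy = iy - jy
        s11 = S11f[C].astype(np.float32)
        s12 = S12f[C].astype(np.float32)
        s22 = S22f[C].astype(np.float32)
        q = s11 * dx * dx + 2.0 * s12 * dx * dy + s22 * dy * dy
        expo = q / denomf[C].astype(np.float32)
        if use_patch:
            Pw32 = (P[C] * w_off).astype(np.float32)
            cross = P[I].astype(np.float32) @ Pw32.T
            expo += np.float32(patch_scale) * (
                p_sq[I].astype(np.float32)[:, None]
                + p_sq[C].astype(np.float32)[None, :]
                - 2.0 * cross
            )
        # screening uses the exponential similarity alone: it is 1 exactly
        # at the pixel itself (zero displacement, identical patch) and in
        # (0, 1] elsewhere, so the threshold T has a fixed meaning and
        # T -> 1 degenerates to the identity; the kept weights below carry
        # the full prefactor before row renormalization
        self_pos = np.searchsorted(C, I)
        expo[np.arange(I.size), self_pos] = 0.0  # exact, despite fp rounding
        Wn = np.exp(-expo)
        W = pref[C].astype(np.float32) * Wn
        kth = min(K, W.shape[1])
        top = np.argpartition(-Wn, kth - 1, axis=1)[:, :kth]
        rows_local = np.arange(I.size)[:, None]
        keep_w = Wn[rows_local, top]
        keep = keep_w > cfg.T
        # the pixel itself is always part of its neighborhood
        is_self = top == self_pos[:, None]
        keep |= is_self
        has_self = is_self.any(axis=1)
        for b in np.flatnonzero(~has_self):
            # self fell outside the top-K: replace the weakest kept slot
            slot = np.argmin(np.where(keep[b], keep_w[b], np.inf))
            top[b, slot] = self_pos[b]
            keep[b, slot] = True
        w_raw = W[rows_local, top] * keep
        sums = w_raw.sum(axis=1, keepdims=True)
        sums[sums <= 0] = 1.0
        w_norm = w_raw / sums
        # rows degenerating to self-only become identity rows
        nk = keep.sum(axis=1)
        only_self = nk <= 1
        if only_self.any():
            w_norm[only_self] = 0.0
            w_norm[only_self, :] = 0.0
            idx = np.flatnonzero(only_self)
            sp_slot = np.argmax(top[idx] == self_pos[idx, None], axis=1)
            w_norm[idx, sp_slot] = 1.0
        kept_mask = w_norm > 0
        rr = np.repeat(I, kept_mask.sum(axis=1))
        cc = C[top[kept_mask]]
        dd = w_norm[kept_mask].astype(np.float64)
        rows_out.append(rr)
        cols_out.append(cc)
        data_out.append(dd)

    H = sp.coo_array(
        (np.concatenate(data_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(npix, npix),
    ).tocsr()
    # exact row normalization (guard against fp drift in the sums above)
    rs = np.asarray(H.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    H = sp.diags_array(1.0 / rs) @ H
    return NonlocalOperator(H=sp.csr_array(H), shape=(ny, nx), cfg=cfg)
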