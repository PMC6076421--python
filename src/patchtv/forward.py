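"""Discrete forward model for straight-line-scanned photoacoustic imaging.

For an ideal point detector at r0, the integrated quantity

    g(r0, t) = (4*pi*Cp*t / beta) * int_0^t p(r0, t') dt'

equals the circular arc integral of the absorption image A over the circle
|r - r0| = c*t.  The discrete forward operator M maps an image (flattened
row-major) to samples g(l, k) for detector l and time bin k by quadrature
along each arc: equally spaced arc points, bilinear deposition onto pixel
centers, each point weighted by its arc-length element (mm).

Signals for experiments are synthesized on a *finer* grid than the one the
solver reconstructs on, so the data never come from the solver's own
discrete operator (no inverse crime).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .phantoms import ImageGrid, PhantomSpec, rasterize

__all__ = [
    "DetectorLine",
    "TimeGrid",
    "ProjectionMatrix",
    "SignalSet",
    "build_projection_matrix",
    "simulate_signals",
    "g_from_pressure",
    "add_noise",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorLine:
    """Uniformly spaced point detectors on a straight line.

    ``orientation``: "parallel-to-y" puts the line vertically at
    x = +distance_to_center (scan from the right of the image);
    "parallel-to-x" puts it horizontally at y = -distance_to_center
    (scan from below).  Lengths in mm.
    """

    n_points: int
    line_length: float
    distance_to_center: float
    orientation: str = "parallel-to-y"

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.line_length < 0:
            raise ValueError("line_length must be >= 0")
        if self.orientation not in ("parallel-to-y", "parallel-to-x"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def positions(self) -> np.ndarray:
        """(n_points, 2) physical (x, y) mm detector coordinates."""
        if self.n_points == 1:
            offs = np.zeros(1)
        else:
            offs = np.linspace(-self.line_length / 2.0, self.line_length / 2.0, self.n_points)
        pos = np.empty((self.n_points, 2))
        if self.orientation == "parallel-to-y":
            pos[:, 0] = self.distance_to_center
            pos[:, 1] = offs
        else:
            pos[:, 0] = offs
            pos[:, 1] = -self.distance_to_center
        return pos


@dataclass(frozen=True)
class TimeGrid:
    """Recording window: sampling frequency fs (Hz), duration (s), start of
    the window t_offset (s) and speed of sound c (m/s)."""

    fs: float
    duration: float
    t_offset: float = 0.0
    c: float = 1500.0

    def __post_init__(self):
        if not (self.fs > 0 and self.duration > 0 and self.c > 0):
            raise ValueError("fs, duration and c must be positive")
        if round(self.fs * self.duration) < 1:
            raise ValueError("time window shorter than one sample")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def times(self) -> np.ndarray:
        return self.t_offset + np.arange(self.n_samples) / self.fs

    @property
    def c_mm(self) -> float:
        """Speed of sound in mm/s."""
        return self.c * 1e3

    def radii(self) -> np.ndarray:
        """Arc radius c*t (mm) of each time bin."""
        return self.c_mm * self.times

    def decimate(self, k: int) -> "TimeGrid":
        """Keep every k-th sample (bounds M's row count)."""
        if k < 1:
            raise ValueError("decimation factor must be >= 1")
        return replace(self, fs=self.fs / k)

    def decimated_to(self, max_bins: int) -> "TimeGrid":
        k = max(1, math.ceil(self.n_samples / max_bins))
        return self.decimate(k)

    @classmethod
    def covering(
        cls,
        det: DetectorLine,
        extent: float,
        fs: float = 200e6,
        c: float = 1500.0,
        duration: float | None = None,
    ) -> "TimeGrid":
        """Window covering every image point from every detector.

        If ``duration`` is given but too short to reach the farthest image
        point, it is extended (with a logged warning): a window that misses
        part of the image makes the limited-view problem unsolvable.
        """
        half = extent / 2.0
        pos = det.positions
        corners = np.array([(sx * half, sy * half) for sx in (-1, 1) for sy in (-1, 1)])
        # farthest point of the square from any detector is one of its corners
        dmax = max(np.hypot(pos[:, 0] - cx, pos[:, 1] - cy).max() for cx, cy in corners)
        # nearest point of the square (0 if a detector lies inside it)
        dmin = 0.0
        inside = (np.abs(pos[:, 0]) <= half) & (np.abs(pos[:, 1]) <= half)
        if not inside.all():
            clx = np.clip(pos[:, 0], -half, half)
            cly = np.clip(pos[:, 1], -half, half)
            dmin = float(np.hypot(pos[:, 0] - clx, pos[:, 1] - cly).min())
        c_mm = c * 1e3
        t0 = dmin / c_mm
        need = (dmax - dmin) / c_mm * 1.01
        if duration is not None and duration < need:
            log.warning(
                "configured duration %.3g us cannot cover the image "
                "(needs %.3g us); extending", duration * 1e6, need * 1e6,
            )
            duration = need
        return cls(fs=fs, duration=duration if duration is not None else need,
                   t_offset=t0, c=c)


@dataclass
class SignalSet:
    """Per-detector time series of the integrated quantity g (n_det, n_t)."""

    values: np.ndarray
    det: DetectorLine
    tg: TimeGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.det.n_points, self.tg.n_samples)
        if self.values.shape != expected:
            raise ValueError(f"signal shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signals must be finite")

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for row in self.values:
                w.writerow([f"{v:.10g}" for v in row])

    @classmethod
    def load_csv(cls, path, det: DetectorLine, tg: TimeGrid) -> "SignalSet":
        with open(path, newline="") as fh:
            values = np.array([[float(v) for v in row] for row in csv.reader(fh)])
        return cls(values=values, det=det, tg=tg)


@dataclass
class ProjectionMatrix:
    """Sparse arc-quadrature operator: (n_det * n_t, nx * ny), weights in mm."""

    matrix: sp.csr_array
    det: DetectorLine
    tg: TimeGrid
    grid_shape: tuple[int, int]  # (ny, nx)
    pixel_size: float
    origin: tuple[float, float]

    _norm_cache: float | None = None

    def apply(self, image: np.ndarray) -> np.ndarray:
        """M @ A: image (ny, nx) or flat -> signals (n_det, n_t)."""
        flat = np.asarray(image, dtype=float).ravel()
        return (self.matrix @ flat).reshape(self.det.n_points, self.tg.n_samples)

    def adjoint(self, signals: np.ndarray) -> np.ndarray:
        """M^T @ g: signals -> image (ny, nx) (backprojection surface)."""
        flat = np.asarray(signals, dtype=float).ravel()
        return (self.matrix.T @ flat).reshape(self.grid_shape)

    @property
    def spectral_norm(self) -> float:
        """Largest singular value, via power iteration (deterministic start)."""
        if self._norm_cache is None:
            n = self.matrix.shape[1]
            v = np.ones(n) / math.sqrt(n)
            for _ in range(40):
                w = self.matrix.T @ (self.matrix @ v)
                nw = np.linalg.norm(w)
                if nw == 0:
                    self._norm_cache = 0.0
                    return 0.0
                v = w / nw
            self._norm_cache = float(math.sqrt(nw))
        return self._norm_cache


def build_projection_matrix(
    grid: ImageGrid,
    det: DetectorLine,
    tg: TimeGrid,
    samples_per_pixel: float = 4.0,
) -> ProjectionMatrix:
    """Assemble the discrete projector M.

    Row (l, k) integrates the image along the circle of radius c*t_k about
    detector l: the circle is sampled at equal angles with at least
    ``samples_per_pixel`` points per crossed pixel, points outside the
    physical image extent are dropped, and each remaining point deposits its
    arc-length element r*dtheta onto the four surrounding pixel centers by
    bilinear weights (clamped at the border half-pixel ring).
    """
    ny, nx = grid.ny, grid.nx
    px = grid.pixel_size
    half_w = nx * px / 2.0
    half_h = ny * px / 2.0
    ox, oy = grid.origin
    radii = tg.radii()
    n_t = tg.n_samples
    pos = det.positions

    # reject geometry/window mismatch: no arc can touch the image
    r_max_possible = radii[-1]
    dmin_any = np.inf
    for x0, y0 in pos:
        clx = min(max(x0, -half_w), half_w)
        cly = min(max(y0, -half_h), half_h)
        dmin_any = min(dmin_any, math.hypot(x0 - clx, y0 - cly))
    if r_max_possible < dmin_any:
        raise ValueError("no arc intersects the image: time window / geometry mismatch")

    blocks = []
    npix = nx * ny
    pos_r = radii[radii > 0]
    if pos_r.size == 0:
        raise ValueError("all arc radii are zero; enlarge the time window")
    # equal-angle sampling: n_k = ceil(2*pi*r / (px / samples_per_pixel))
    n_samp = np.maximum(8, np.ceil(2 * np.pi * radii / (px / samples_per_pixel)).astype(int))
    n_samp[radii <= 0] = 0
    total = int(n_samp.sum())
    bin_of = np.repeat(np.arange(n_t), n_samp)
    starts = np.concatenate([[0], np.cumsum(n_samp)[:-1]])
    local = np.arange(total) - np.repeat(starts, n_samp)
    dtheta = np.repeat(np.where(n_samp > 0, 2 * np.pi / np.maximum(n_samp, 1), 0.0), n_samp)
    theta = local * dtheta
    r_of = np.repeat(radii, n_samp)
    wq = r_of * dtheta  # arc-length element per sample (mm)
    cxs, sxs = np.cos(theta), np.sin(theta)

    for x0, y0 in pos:
        X = x0 + r_of * cxs
        Y = y0 + r_of * sxs
        # keep samples inside the pixel-center bounding box (the bilinear
        # interpolation domain); samples in the outer half-pixel ring are
        # dropped -- folding them onto border pixels would give the border
        # columns enormous spurious weight
        fx_all = (X - ox) / px
        fy_all = (oy - Y) / px
        inside = (fx_all >= 0) & (fx_all <= nx - 1) & (fy_all >= 0) & (fy_all <= ny - 1)
        fx, fy = fx_all[inside], fy_all[inside]
        Wi, Bi = wq[inside], bin_of[inside]
        ix0 = np.minimum(fx.astype(int), nx - 2)
        iy0 = np.minimum(fy.astype(int), ny - 2)
        tx = fx - ix0
        ty = fy - iy0
        base = iy0 * nx + ix0
        cols = np.concatenate([base, base + 1, base + nx, base + nx + 1])
        rows = np.concatenate([Bi, Bi, Bi, Bi])
        data = np.concatenate(
            [Wi * (1 - tx) * (1 - ty), Wi * tx * (1 - ty), Wi * (1 - tx) * ty, Wi * tx * ty]
        )
        block = sp.coo_array((data, (rows, cols)), shape=(n_t, npix)).tocsr()
        blocks.append(block)

    matrix = sp.vstack(blocks, format="csr")
    return ProjectionMatrix(
        matrix=matrix, det=det, tg=tg, grid_shape=(ny, nx),
        pixel_size=px, origin=grid.origin,
    )


def simulate_signals(
    spec: PhantomSpec,
    det: DetectorLine,
    tg: TimeGrid,
    base_nx: int = 128,
    supersample: int = 2,
    samples_per_pixel: float = 4.0,
) -> SignalSet:
    """Synthesize g on a grid ``supersample`` times finer than ``base_nx``.

    The projector built here lives on the fine grid and is never the one a
    solver reconstructs with, avoiding the inverse crime.
    """
    if supersample < 2:
        raise ValueError("supersample must be >= 2 (data on a finer grid than reconstruction)")
    n = base_nx * supersample
    fine = rasterize(spec, n, n, supersample=2)
    M = build_projection_matrix(fine, det, tg, samples_per_pixel=samples_per_pixel)
    return SignalSet(values=M.apply(fine.values), det=det, tg=tg)


def g_from_pressure(
    p: np.ndarray, tg: TimeGrid, Cp: float, beta_exp: float
) -> SignalSet:
    """Integrated quantity g(l, t_k) = (4*pi*Cp*t_k/beta) * int_0^{t_k} p dt.

    ``p`` is the (n_det, n_t) pressure record sampled on ``tg.times`` (the
    record is assumed to start the integration window, i.e. covers 0..t when
    t_offset = 0).  Trapezoidal cumulative quadrature.
    """
    from scipy.integrate import cumulative_trapezoid

    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    if not (Cp > 0 and beta_exp > 0):
        raise ValueError("Cp and beta_exp must be positive")
    t = tg.times
    if p.shape[-1] != t.size:
        raise ValueError(f"pressure has {p.shape[-1]} samples, time grid {t.size}")
    integral = cumulative_trapezoid(p, x=t, axis=-1, initial=0.0)
    g = (4.0 * np.pi * Cp / beta_exp) * t * integral
    det = DetectorLine(n_points=p.shape[0], line_length=max(p.shape[0] - 1, 0) * 1.0,
                       distance_to_center=0.0)
    return SignalSet(values=np.atleast_2d(g), det=det, tg=tg)


def add_noise(g: SignalSet, snr_db: float, seed: int) -> SignalSet:
    """Add i.i.d. zero-mean Gaussian noise at the requested SNR (dB).

    Noise variance = (mean signal power over all samples) / 10^(snr_db/10);
    reproducible for a given seed.  snr_db = +inf returns an exact copy.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return SignalSet(values=g.values.copy(), det=g.det, tg=g.tg)
    power = float(np.mean(g.values**2))
    if power == 0.0:
        raise ValueError("zero-power signal: SNR is undefined")
    sigma = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = g.values + rng.normal(0.0, sigma, size=g.values.shape)
    return SignalSet(values=noisy, det=g.det, tg=g.tg)
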