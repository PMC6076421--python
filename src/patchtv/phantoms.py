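"""Analytic ellipse phantoms and their rasterization.

The absorption distribution A(r) is modelled as a finite sum of constant
ellipses: inside each ellipse the given intensity is *added* to the image
(the standard Shepp--Logan convention, so nested ellipses produce the
familiar plateaus).  Phantoms are defined in physical millimetres on a
square field of view centered at the origin, x rightward, y upward.  When
rasterized, pixel (0, 0) sits at the top-left: row index runs along -y,
column index along +x, and ``origin`` is the physical coordinate of the
center of pixel (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "EllipseSpec",
    "PhantomSpec",
    "ImageGrid",
    "make_shepp_logan",
    "make_forbild",
    "rasterize",
]


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: ``center``/``semi_axes`` in mm, ``rotation`` in radians
    (counter-clockwise, normalized to [0, 2pi)), additive ``intensity``."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    intensity: float

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError(f"semi_axes must be strictly positive, got {self.semi_axes}")
        rot = float(self.rotation) % (2.0 * math.pi)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "semi_axes", (float(a), float(b)))
        object.__setattr__(self, "intensity", float(self.intensity))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points (x, y) inside (or on) the ellipse."""
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        ct, st = math.cos(self.rotation), math.sin(self.rotation)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ordered list of ellipses on a square field of view of width ``extent`` mm."""

    ellipses: tuple[EllipseSpec, ...]
    extent: float

    def __post_init__(self):
        if not self.extent > 0:
            raise ValueError("extent must be positive")
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        object.__setattr__(self, "extent", float(self.extent))

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic A(r) at physical points (x, y) in mm; overlaps add."""
        out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, dtype=float)
        for e in self.ellipses:
            out += e.intensity * e.contains(x, y)
        return out

    def scaled_intensities(self, c: float) -> "PhantomSpec":
        return replace(
            self,
            ellipses=tuple(replace(e, intensity=c * e.intensity) for e in self.ellipses),
        )

    @property
    def max_value(self) -> float:
        """Upper bound on attainable pixel values (peak of the nested sums).

        Evaluated on a dense probe grid; exact for the shipped phantoms whose
        plateau regions are far larger than the probe spacing.
        """
        n = 512
        half = self.extent / 2.0
        xs = np.linspace(-half, half, n)
        X, Y = np.meshgrid(xs, xs)
        return float(self.evaluate(X, Y).max())

    # -- plain-text round trip -------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "extent_mm": self.extent,
            "ellipses": [
                {
                    "center": [e.center[0], e.center[1]],
                    "axes": [e.semi_axes[0], e.semi_axes[1]],
                    "angle_deg": math.degrees(e.rotation),
                    "intensity": e.intensity,
                }
                for e in self.ellipses
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        doc = yaml.safe_load(text)
        ellipses = tuple(
            EllipseSpec(
                center=tuple(d["center"]),
                semi_axes=tuple(d["axes"]),
                rotation=math.radians(d["angle_deg"]),
                intensity=d["intensity"],
            )
            for d in doc["ellipses"]
        )
        return cls(ellipses=ellipses, extent=float(doc["extent_mm"]))


@dataclass
class ImageGrid:
    """Square-pixel 2D image with physical placement.

    ``values`` has shape (ny, nx); row 0 is the top of the image (largest y).
    ``origin`` is the physical (x, y) mm coordinate of the center of pixel
    (0, 0).
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("image must be at least 2x2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> float:
        return self.nx * self.pixel_size

    def x_coords(self) -> np.ndarray:
        """Physical x of each column's pixel centers."""
        return self.origin[0] + self.pixel_size * np.arange(self.nx)

    def y_coords(self) -> np.ndarray:
        """Physical y of each row's pixel centers (decreasing)."""
        return self.origin[1] - self.pixel_size * np.arange(self.ny)

    def save_npy(self, path) -> None:
        np.save(path, self.values)

    def save_png(self, path) -> None:
        """8-bit PNG, max-normalized for display only."""
        from PIL import Image

        v = self.values
        peak = np.abs(v).max()
        disp = np.clip(v / peak, 0.0, 1.0) if peak > 0 else np.zeros_like(v)
        Image.fromarray((disp * 255).round().astype(np.uint8)).save(path)

    @classmethod
    def load_npy(cls, path, pixel_size: float, origin=None) -> "ImageGrid":
        values = np.load(path)
        if origin is None:
            ny, nx = values.shape
            origin = (-(nx - 1) / 2.0 * pixel_size, (ny - 1) / 2.0 * pixel_size)
        return cls(values=values, pixel_size=pixel_size, origin=tuple(origin))


# Modified (Toft) Shepp--Logan parameter table in the unit square
# [-1, 1]^2: (x0, y0, a, b, angle_deg, intensity).
_SHEPP_LOGAN = [
    (0.0, 0.0, 0.69, 0.92, 0.0, 1.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.8),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.2),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.2),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.1),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.1),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.1),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.1),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.1),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.1),
]

# Ellipse-only head phantom standing in for the FORBILD head (synthetic:
# the full FORBILD definition mixes ellipses with other primitives; this
# stand-in keeps the nested-intensity structure -- bright skull shell, soft
# brain interior, ventricles, small high/low-contrast inserts -- at matching
# complexity).  Unit-square coordinates as above.
_FORBILD_LIKE = [
    (0.0, 0.0, 0.92, 0.78, 0.0, 1.80),     # skull shell
    (0.0, 0.0, 0.86, 0.72, 0.0, -0.75),    # brain interior -> 1.05
    (-0.62, -0.05, 0.10, 0.20, 0.30, -1.05),  # air cavity (ear) -> 0
    (0.25, 0.48, 0.09, 0.11, 0.0, 0.04),   # right eye
    (-0.25, 0.48, 0.09, 0.11, 0.0, 0.04),  # left eye
    (0.14, 0.05, 0.24, 0.08, -1.0, -0.10),  # right ventricle -> 0.95
    (-0.14, 0.05, 0.24, 0.08, 1.0, -0.10),  # left ventricle -> 0.95
    (0.30, -0.35, 0.05, 0.05, 0.0, 0.30),  # high-contrast lesion
    (-0.28, -0.40, 0.06, 0.03, 0.5, 0.20),  # slanted lesion
    (0.0, -0.60, 0.28, 0.05, 0.0, 0.15),   # thin basal structure
]


def _from_unit_table(table, extent: float) -> PhantomSpec:
    s = extent / 2.0
    ellipses = tuple(
        EllipseSpec(
            center=(x0 * s, y0 * s),
            semi_axes=(a * s, b * s),
            rotation=math.radians(ang),
            intensity=inten,
        )
        for (x0, y0, a, b, ang, inten) in table
    )
    return PhantomSpec(ellipses=ellipses, extent=extent)


def make_shepp_logan(extent: float = 76.8) -> PhantomSpec:
    """Standard 10-ellipse (modified intensity) Shepp--Logan head phantom,
    scaled to a ``extent`` x ``extent`` mm field of view (default 76.8 mm)."""
    return _from_unit_table(_SHEPP_LOGAN, extent)


def make_forbild(extent: float = 76.8) -> PhantomSpec:
    """FORBILD-head-style phantom (ellipse-only synthetic stand-in), scaled
    to a ``extent`` x ``extent`` mm field of view."""
    return _from_unit_table(_FORBILD_LIKE, extent)


def rasterize(spec: PhantomSpec, nx: int, ny: int, supersample: int = 1) -> ImageGrid:
    """Rasterize the analytic phantom onto an nx x ny pixel grid.

    Each pixel value is the mean of A(r) over ``supersample``^2 equally
    spaced sub-points inside the pixel (supersample=1 samples the pixel
    center).  Deterministic.
    """
    if nx < 2 or ny < 2:
        raise ValueError("nx, ny must be >= 2")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    px = spec.extent / nx
    origin = (-(nx - 1) / 2.0 * px, (ny - 1) / 2.0 * px)
    xs = origin[0] + px * np.arange(nx)
    ys = origin[1] - px * np.arange(ny)
    # sub-pixel offsets: centers of an s x s partition of the pixel
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5  # in pixel units
    values = np.zeros((ny, nx), dtype=float)
    for oy in offs:
        for ox in offs:
            X, Y = np.meshgrid(xs + ox * px, ys - oy * px)
            values += spec.evaluate(X, Y)
    values /= s * s
    return ImageGrid(values=values, pixel_size=px, origin=origin)
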