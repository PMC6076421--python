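"""Image-quality and convergence metrics.

PSNR = 10 log10( Nx*Ny*MAXI^2 / sum (A - R)^2 )  [dB], computed on
un-normalized images; MAXI defaults to the peak of the reference.
d = sqrt( sum (A - R)^2 / sum R^2 ) is the relative distance used for the
convergence curves.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .phantoms import ImageGrid

__all__ = ["MetricReport", "psnr", "distance_d", "normalize_for_display",
           "write_metrics_csv"]


def _values(A) -> np.ndarray:
    return A.values if isinstance(A, ImageGrid) else np.asarray(A, dtype=float)


@dataclass(frozen=True)
class MetricReport:
    psnr: float
    distance_d: float
    maxi: float


def psnr(A, R, maxi: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a, r = _values(A), _values(R)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {r.shape}")
    if maxi is None:
        maxi = float(r.max())
    if not maxi > 0:
        raise ValueError("maxi must be positive")
    sse = float(((a - r) ** 2).sum())
    if sse == 0.0:
        return float("inf")
    return 10.0 * np.log10(a.size * maxi**2 / sse)


def distance_d(A, R) -> float:
    """Relative Euclidean distance between reconstruction and reference."""
    a, r = _values(A), _values(R)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {r.shape}")
    denom = float((r**2).sum())
    if denom == 0.0:
        raise ValueError("all-zero reference")
    return float(np.sqrt(((a - r) ** 2).sum() / denom))


def report(A, R, maxi: float | None = None) -> MetricReport:
    m = float(_values(R).max()) if maxi is None else float(maxi)
    return MetricReport(psnr=psnr(A, R, m), distance_d=distance_d(A, R), maxi=m)


def normalize_for_display(A):
    """Divide by the maximum value (display only; never applied before
    PSNR).  Idempotent; rejects an all-zero image."""
    v = _values(A)
    peak = float(v.max())
    if peak == 0.0 and float(np.abs(v).max()) == 0.0:
        raise ValueError("cannot normalize an all-zero image")
    if peak == 0.0:
        raise ValueError("cannot normalize an image with non-positive maximum")
    out = v / peak
    if isinstance(A, ImageGrid):
        return ImageGrid(values=out, pixel_size=A.pixel_size, origin=A.origin)
    return out


def write_metrics_csv(path, rows: list[dict]) -> None:
    """Append-style CSV log (experiment, solver, n_points, snr_db, psnr_db,
    d_final, iters)."""
    cols = ["experiment", "solver", "n_points", "snr_db", "psnr_db", "d_final", "iters"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in rows:
            w.writerow({k: row.get(k, "") for k in cols})
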