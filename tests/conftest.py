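import math

import numpy as np
import pytest

from patchtv import (
    DetectorLine,
    EllipseSpec,
    PhantomSpec,
    TimeGrid,
    build_projection_matrix,
    make_shepp_logan,
    rasterize,
    simulate_signals,
)


@pytest.fixture(scope="session")
def shepp_spec():
    return make_shepp_logan()


@pytest.fixture(scope="session")
def disk_spec():
    """Single off-center disk, radius much smaller than the field of view."""
    return PhantomSpec(
        ellipses=(EllipseSpec(center=(5.0, -8.0), semi_axes=(6.0, 6.0),
                              rotation=0.0, intensity=1.0),),
        extent=76.8,
    )


@pytest.fixture(scope="session")
def disk_setup(disk_spec):
    """32x32 reconstruction problem for a small disk: truth, M, signals."""
    truth = rasterize(disk_spec, 32, 32, supersample=2)
    det = DetectorLine(n_points=20, line_length=76.0, distance_to_center=38.0)
    tg = TimeGrid.covering(det, 76.8).decimated_to(128)
    M = build_projection_matrix(truth, det, tg)
    g = simulate_signals(disk_spec, det, tg, base_nx=32, supersample=2)
    return dict(spec=disk_spec, truth=truth, det=det, tg=tg, M=M, g=g)


@pytest.fixture(scope="session")
def shepp64_setup(shepp_spec):
    """64x64 Shepp--Logan line-scan problem (50 detectors)."""
    truth = rasterize(shepp_spec, 64, 64, supersample=2)
    det = DetectorLine(n_points=50, line_length=76.0, distance_to_center=38.0)
    tg = TimeGrid.covering(det, 76.8).decimated_to(256)
    M = build_projection_matrix(truth, det, tg)
    g = simulate_signals(shepp_spec, det, tg, base_nx=64, supersample=2)
    return dict(spec=shepp_spec, truth=truth, det=det, tg=tg, M=M, g=g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_block_image():
    """Flat background with two identical distant texture blocks."""
    img = np.zeros((40, 40))
    block = np.array([[1.0, 0.2, 0.8], [0.1, 0.9, 0.3], [0.7, 0.4, 1.0]])
    img[5:8, 5:8] = block
    img[30:33, 28:31] = block
    return img


def brute_force_tv(v):
    """Elementwise double-loop TV oracle, zero across the boundary."""
    ny, nx = v.shape
    total = 0.0
    for m in range(ny):
        for n in range(nx):
            dy = v[m, n] - v[m - 1, n] if m > 0 else 0.0
            dx = v[m, n] - v[m, n - 1] if n > 0 else 0.0
            total += math.sqrt(dy * dy + dx * dx)
    return total
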