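"""Config-driven experiment runner: phantom -> simulated signals ->
reconstructions -> metric CSV and images, fully deterministic under a seed.

A YAML experiment config names a phantom (shepp_logan / forbild / a path to
a phantom YAML), the reconstruction grid, the detector-line geometry, the
time sampling, the solver list with their parameters, the sampling-point
sweep and optionally a noise sweep.  ``run_experiment`` executes the full
grid and writes one CSV row per (solver, n_points, snr) cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics
from .forward import DetectorLine, TimeGrid, add_noise, build_projection_matrix, simulate_signals
from .patches import PatchConfig
from .phantoms import PhantomSpec, make_forbild, make_shepp_logan, rasterize
from .solvers import (
    SolverParams,
    backprojection,
    patch_re_reconstruct,
    patch_tv_reconstruct,
    tv_gd_reconstruct,
)

__all__ = ["ExperimentConfig", "run_experiment", "plot_convergence", "load_config",
           "bundled_config_path"]

log = logging.getLogger(__name__)

_SOLVERS = ("patch_tv", "tv_gd", "patch_re", "backprojection")


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    name: str
    phantom: str = "shepp_logan"
    nx: int = 128
    ny: int = 128
    extent: float = 76.8
    detector: dict = field(default_factory=lambda: dict(
        line_length_mm=76.0, distance_mm=38.0, orientation="parallel-to-y"))
    time: dict = field(default_factory=lambda: dict(
        fs_hz=200e6, duration_s=20e-6, c_mps=1500.0, max_bins=512))
    sampling_points: list = field(default_factory=lambda: [50, 20, 10])
    solvers: list = field(default_factory=lambda: list(_SOLVERS))
    params: dict = field(default_factory=dict)       # per-solver SolverParams fields
    patch: dict = field(default_factory=dict)        # PatchConfig fields
    noise_snr_db: list | None = None
    seed: int = 0
    supersample: int = 2
    iterations: int = 10

    def validate(self) -> None:
        for s in self.solvers:
            if s not in _SOLVERS:
                raise ConfigError(f"solvers: unknown solver {s!r}")
        if any(p <= 0 for p in self.sampling_points):
            raise ConfigError("sampling_points: entries must be positive")
        if self.nx < 2 or self.ny < 2:
            raise ConfigError("grid: nx and ny must be >= 2")

    # ------------------------------------------------------------------
    def phantom_spec(self) -> PhantomSpec:
        if self.phantom == "shepp_logan":
            return make_shepp_logan(self.extent)
        if self.phantom == "forbild":
            return make_forbild(self.extent)
        path = Path(self.phantom)
        if not path.exists():
            raise ConfigError(f"phantom: no such phantom or file {self.phantom!r}")
        return PhantomSpec.from_yaml(path.read_text())

    def detector_line(self, n_points: int) -> DetectorLine:
        d = self.detector
        return DetectorLine(
            n_points=n_points,
            line_length=float(d.get("line_length_mm", 76.0)),
            distance_to_center=float(d.get("distance_mm", 38.0)),
            orientation=d.get("orientation", "parallel-to-y"),
        )

    def time_grid(self, det: DetectorLine) -> TimeGrid:
        t = self.time
        tg = TimeGrid.covering(
            det,
            self.extent,
            fs=float(t.get("fs_hz", 200e6)),
            c=float(t.get("c_mps", 1500.0)),
            duration=float(t["duration_s"]) if "duration_s" in t else None,
        )
        return tg.decimated_to(int(t.get("max_bins", 512)))

    def solver_params(self, solver: str) -> SolverParams:
        base = dict(self.params.get("default", {}))
        base.update(self.params.get(solver, {}))
        base.setdefault("max_iters", self.iterations)
        allowed = {"alpha", "beta", "max_iters", "epsilon", "sigma0"}
        bad = set(base) - allowed
        if bad:
            raise ConfigError(f"params.{solver}: unknown fields {sorted(bad)}")
        return SolverParams(**base)

    def patch_config(self) -> PatchConfig:
        p = dict(self.patch)
        rename = {"tensor_sigma": "tensor_smoothing", "stride": "candidate_stride"}
        for old, new in rename.items():
            if old in p:
                p[new] = p.pop(old)
        allowed = {f.name for f in PatchConfig.__dataclass_fields__.values()}
        bad = set(p) - set(allowed)
        if bad:
            raise ConfigError(f"patch: unknown fields {sorted(bad)}")
        return PatchConfig(**p)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> ExperimentConfig:
    doc = yaml.safe_load(Path(path).read_text())
    known = set(ExperimentConfig.__dataclass_fields__)
    grid = doc.pop("grid", None)
    if grid:
        doc["nx"] = int(grid.get("nx", 128))
        doc["ny"] = int(grid.get("ny", 128))
        if "extent_mm" in grid:
            doc["extent"] = float(grid["extent_mm"])
    bad = set(doc) - known
    if bad:
        raise ConfigError(f"unknown config fields {sorted(bad)}")
    cfg = ExperimentConfig(**doc)
    cfg.validate()
    return cfg


def bundled_config_path(name: str) -> Path:
    """Path of a shipped experiment config (e.g. 'shepp_perpendicular')."""
    from importlib.resources import files

    p = files("patchtv") / "configs" / f"{name}.yaml"
    return Path(str(p))


def _reconstruct(solver, g, M, params, patch_cfg, reference):
    if solver == "patch_tv":
        return patch_tv_reconstruct(g, M, params, patch_cfg, reference)
    if solver == "tv_gd":
        return tv_gd_reconstruct(g, M, params, reference)
    if solver == "patch_re":
        return patch_re_reconstruct(g, M, params, patch_cfg, reference)
    if solver == "backprojection":
        res = backprojection(g, M)
        if reference is not None:
            res.d_per_iter = [metrics.distance_d(res.image.values, reference)]
        return res
    raise ConfigError(f"unknown solver {solver!r}")


def run_experiment(cfg: ExperimentConfig, outdir, seed: int | None = None) -> dict:
    """Run the full (solver x sampling x noise) grid of an experiment.

    Writes <outdir>/metrics.csv, reconstructed images as .npy and .png and a
    run manifest; returns {cell_key: ReconResult-like dict}.  Deterministic
    for a fixed seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    spec = cfg.phantom_spec()
    truth = rasterize(spec, cfg.nx, cfg.ny, supersample=2)
    maxi = float(truth.values.max())
    patch_cfg = cfg.patch_config()
    snrs = cfg.noise_snr_db if cfg.noise_snr_db else [None]

    rows = []
    results = {}
    for n_points in cfg.sampling_points:
        det = cfg.detector_line(n_points)
        tg = cfg.time_grid(det)
        g_clean = simulate_signals(spec, det, tg, base_nx=cfg.nx,
                                   supersample=cfg.supersample)
        M = build_projection_matrix(truth, det, tg)
        for snr in snrs:
            g = g_clean if snr is None else add_noise(
                g_clean, snr, seed=seed + 1000 * n_points + int(snr))
            for solver in cfg.solvers:
                params = cfg.solver_params(solver)
                res = _reconstruct(solver, g, M, params, patch_cfg, truth.values)
                p = metrics.psnr(res.image.values, truth.values, maxi)
                d = metrics.distance_d(res.image.values, truth.values)
                key = f"{solver}_{n_points}pts" + ("" if snr is None else f"_snr{snr}")
                res.image.save_npy(outdir / f"{key}.npy")
                res.image.save_png(outdir / f"{key}.png")
                rows.append(dict(
                    experiment=cfg.name, solver=solver, n_points=n_points,
                    snr_db="" if snr is None else snr,
                    psnr_db=f"{p:.4f}", d_final=f"{d:.6f}", iters=res.iters_run,
                ))
                results[key] = dict(
                    solver=solver, n_points=n_points, snr_db=snr, psnr=p, d=d,
                    d_per_iter=res.d_per_iter,
                    objective_per_iter=res.objective_per_iter,
                    image=res.image,
                )
                log.info("%s %s: PSNR=%.2f dB d=%.4f", cfg.name, key, p, d)

    metrics.write_metrics_csv(outdir / "metrics.csv", rows)
    manifest = dict(name=cfg.name, config_hash=cfg.digest(), seed=seed)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    truth.save_npy(outdir / "truth.npy")
    truth.save_png(outdir / "truth.png")
    return results


def plot_convergence(results: dict, path) -> None:
    """One d-vs-iteration line per solver (Fig.-8-style convergence chart)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = {k: v for k, v in results.items() if v.get("d_per_iter")}
    if not series:
        raise ValueError("no convergence records (d_per_iter) in results")
    fig, ax = plt.subplots(figsize=(6, 4))
    for key, rec in sorted(series.items()):
        d = rec["d_per_iter"]
        ax.plot(range(1, len(d) + 1), d, marker="o", label=key)
    ax.set_xlabel("iteration")
    ax.set_ylabel("distance d")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
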