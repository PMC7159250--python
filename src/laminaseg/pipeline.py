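"""End-to-end orchestration: simulate → profiles → train → segment →
reconstruct → morphometry → gradients, with a hashed artifact manifest so a
run is reproducible bit for bit under a fixed configuration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry as mm
from . import network as net
from . import profiles as pg
from . import reconstruction as rec
from . import synthetic as syn
from .io_formats import write_surface, write_table, write_volume

log = logging.getLogger("laminaseg")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one reproducible phantom run."""

    out_dir: str = "laminaseg_run"
    seed: int = 0
    # phantom
    grid_size: int = 64
    voxel_size_um: float = 100.0
    folding_amplitude_mm: float = 0.5
    mesh_resolution: int = 16
    curvature_thinning: float = 0.0
    texture_sd: float = 0.05
    staining_slope: float = 0.0
    # training
    n_train_profiles: int = 600
    network: dict = field(default_factory=lambda: dict(
        n_blocks=3, filter_size=25, n_feature_maps=12,
        learning_rate=0.1, weight_decay=0.001, batch_size=64,
        patience_epochs=8, max_epochs=20))
    # geometry
    smoothing: dict = field(default_factory=dict)
    # morphometry
    apply_shrinkage: bool = False
    index_fwhm_mm: float = 0.5
    taubin_iterations: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the full phantom pipeline; returns the manifest dict.

    Artifacts (volumes, meshes, thickness table, gradient table, confidence
    map, manifest.json) are written to ``cfg.out_dir``. Re-running with the
    same config reproduces identical manifest hashes.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, str] = {}
    timers: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                start = time.time()
                log.info("stage %s ...", name)
                try:
                    result = fn(*a, **kw)
                except Exception as exc:
                    raise StageError(name, exc) from exc
                timers[name] = round(time.time() - start, 2)
                return result
            return wrapped
        return deco

    spec = syn.SyntheticCortexSpec(
        layer_specs=syn._default_layers(cfg.texture_sd),
        staining_slope=cfg.staining_slope, seed=cfg.seed)

    @stage("simulate")
    def _simulate():
        return syn.generate_cortical_sheet(
            spec, folding_amplitude_mm=cfg.folding_amplitude_mm,
            grid_size=cfg.grid_size, voxel_size_um=cfg.voxel_size_um,
            mesh_resolution=cfg.mesh_resolution,
            curvature_thinning=cfg.curvature_thinning, seed=cfg.seed)

    vol, pial, white, labels, truth_thick = _simulate()
    write_volume(vol, out / "phantom.nii.gz")
    artifacts["phantom.nii.gz"] = _sha256(out / "phantom.nii.gz")

    smooth_cfg = pg.SmoothingConfig(**cfg.smoothing)

    @stage("profiles")
    def _profiles():
        smoothed = pg.anisotropic_smooth(vol, smooth_cfg)
        pair = pg.SurfacePair(pial, white)
        mid = pg.compute_midsurface(pair)
        lines = pg.compute_streamlines(pair, mid, smooth_cfg)
        profs = pg.sample_profiles(vol, lines, smoothed=smoothed)
        profs = pg.normalize_ap_gradient(profs)
        return mid, lines, profs

    mid, lines, profs = _profiles()

    @stage("train")
    def _train():
        tset = syn.generate_training_set(spec, cfg.n_train_profiles,
                                         seed=cfg.seed + 1)
        clf = net.ProfileLayerClassifier(random_state=cfg.seed,
                                         **cfg.network)
        clf.fit(tset.x, tset.labels)
        return clf

    clf = _train()

    @stage("segment")
    def _segment():
        x = np.stack([[p.raw, p.smoothed] for p in profs])
        pm = net.predict(clf.network_, x)
        return pm, net.confidence(pm)

    pm, conf = _segment()

    @stage("reconstruct")
    def _reconstruct():
        b = rec.locate_all_transitions(pm.argmax_labels)
        b = rec.interpolate_failed(b, mid)
        b = rec.smooth_boundary_indices(b, mid, cfg.index_fwhm_mm)
        ss = rec.indices_to_surfaces(b, lines, mid.triangles)
        ss = rec.SurfaceSet([rec.taubin_smooth(s, cfg.taubin_iterations)
                             for s in ss.surfaces])
        return b, ss

    boundaries, surfaces = _reconstruct()
    for name, s in zip(rec.SURFACE_NAMES, surfaces.surfaces):
        path = out / f"{name}.surf.gii"
        write_surface(s, path)
        artifacts[path.name] = _sha256(path)

    @stage("morphometry")
    def _morphometry():
        ss = surfaces
        if cfg.apply_shrinkage:
            ss = mm.apply_shrinkage(ss, mm.ShrinkageFactors())
        tmap = mm.thickness(ss)
        df = pd.DataFrame({"vertex": np.arange(len(tmap.total)),
                           "total_mm": tmap.total,
                           "truth_mm": truth_thick})
        for i, lname in enumerate(mm.LAYER_NAMES):
            df[f"layer_{lname}_mm"] = tmap.laminar[:, i]
        df["confidence"] = conf.per_vertex
        df["failed"] = boundaries.failed_mask
        write_table(df, out / "thickness.csv")
        return tmap

    tmap = _morphometry()
    artifacts["thickness.csv"] = _sha256(out / "thickness.csv")

    @stage("gradients")
    def _gradients():
        x = mid.vertices[:, 0]
        primary = x <= np.quantile(x, 0.15)
        dist = mm.geodesic_distance(mid, primary)
        region = np.ones(len(x), dtype=bool)
        res = mm.gradient_analysis(tmap, dist, region, system="phantom",
                                   window_mm=1.0, step_mm=0.5)
        rows = [{"system": res.system, "target": "total",
                 "r": res.r, "p": res.p, "n": res.n}]
        for i, lname in enumerate(mm.LAYER_NAMES):
            rows.append({"system": res.system, "target": f"layer_{lname}",
                         "r": res.per_layer_r[i], "p": res.per_layer_p[i],
                         "n": res.n})
        write_table(pd.DataFrame(rows), out / "gradients.csv")
        return res

    _gradients()
    artifacts["gradients.csv"] = _sha256(out / "gradients.csv")

    manifest = {
        "config": asdict(cfg),
        "artifacts": artifacts,
        "stage_seconds": timers,
        "total_seconds": round(time.time() - t0, 2),
        "mean_abs_thickness_error_mm": float(
            np.abs(tmap.total - truth_thick).mean()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def validate_run(artifact_dir: str | Path) -> tuple[pd.DataFrame, bool]:
    """Consistency checks on a completed run: artifact hashes, surface
    nesting/additivity, non-negative thickness, confidence bounds, failed-
    vertex accounting. Returns (report with one row per check, all_passed).
    """
    out = Path(artifact_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    rows = []

    def check(name: str, ok: bool, detail: str = "") -> None:
        rows.append({"check": name, "passed": bool(ok), "detail": detail})

    hashes_ok = all((out / f).exists() and _sha256(out / f) == h
                    for f, h in manifest["artifacts"].items())
    check("artifact_hashes", hashes_ok)

    df = pd.read_csv(out / "thickness.csv")
    lam = df[[f"layer_{n}_mm" for n in mm.LAYER_NAMES]].to_numpy()
    total = df["total_mm"].to_numpy()
    check("thickness_nonnegative", bool((total >= 0).all() and (lam >= 0).all()))
    add_err = np.abs(lam.sum(axis=1) - total).max()
    check("thickness_additivity", add_err < 1e-6, f"max err {add_err:.2e}")
    conf = df["confidence"].to_numpy()
    check("confidence_bounds", bool(((conf >= 0) & (conf <= 1)).all()))
    frac_failed = df["failed"].mean()
    check("failed_fraction_lt_10pct", frac_failed < 0.10,
          f"{frac_failed:.2%}")
    report = pd.DataFrame(rows)
    return report, bool(report["passed"].all())
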