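"""End-to-end pipeline stages driven by a YAML run configuration.

Every stage is deterministic given the config and the global seed, writes
its products under ``out_dir``, and records a manifest JSON listing the
inputs, parameters, seed, and SHA-256 hashes of the outputs, so any
artifact on disk is regenerable from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import (
    DetectionParams,
    bottom_hat_detect,
    score_detection,
    size_stratified_fscore,
    threshold_sweep,
    windowed_spectrum,
)
from .forward import HRImage, LRStack
from .geometry import VoxelGrid
from .io import (
    read_geometries,
    read_stack,
    read_volume,
    sha256_file,
    write_geometries,
    write_stack,
    write_volume,
)
from .phantom import (
    PhantomTruth,
    container_mask,
    default_phantom_spec,
    default_study_geometry,
    generate_phantom,
    simulate_study,
)
from .solver import SRRConfig, initialize_estimate, reconstruct
from .voi import voi_from_signal

log = logging.getLogger("locsrr")

COMMANDS = ("phantom", "simulate", "reconstruct", "voi", "detect", "evaluate", "spectra")


@dataclass
class RunConfig:
    """Parsed run configuration; see ``RunConfig.from_yaml``."""

    out_dir: Path
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        out_dir = Path(doc.get("out_dir", "locsrr_out"))
        return cls(out_dir=out_dir, seed=int(doc.get("seed", 0)), options=doc)

    def section(self, name: str) -> dict:
        return dict(self.options.get(name, {}) or {})


def _write_manifest(cfg: RunConfig, command: str, params: dict, outputs: list[Path]) -> Path:
    manifest = {
        "command": command,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": params,
        "outputs": {str(p.name): sha256_file(p) for p in outputs if p.exists()},
    }
    path = cfg.out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _detection_params(opts: dict) -> DetectionParams:
    kw = {}
    for key in ("se_size", "percentile", "slice_axis", "boundary_margin_vox", "min_size_vox"):
        if key in opts:
            kw[key] = opts[key]
    if "percentiles" in opts:
        kw["percentiles"] = tuple(opts["percentiles"])
    return DetectionParams(**kw)


def _load_stacks(cfg: RunConfig, opts: dict) -> list[LRStack]:
    geom_path = opts.get("geometry", str(cfg.out_dir / "geometry.json"))
    geoms = read_geometries(geom_path)
    paths = opts.get("stacks") or [
        str(cfg.out_dir / f"stack_{i:02d}.nii.gz") for i in range(len(geoms))
    ]
    if len(paths) != len(geoms):
        raise ValueError(
            f"{len(paths)} stack paths but {len(geoms)} geometry entries"
        )
    return [read_stack(p, g) for p, (g, _origin) in zip(paths, geoms)]


def run_pipeline(cfg: RunConfig, command: str) -> Path:
    """Execute one pipeline stage; returns the manifest path."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    handler = globals()[f"_cmd_{command}"]
    try:
        params, outputs = handler(cfg)
    except Exception:
        log.exception("stage %r failed", command)
        raise
    return _write_manifest(cfg, command, params, outputs)


def _cmd_phantom(cfg: RunConfig):
    opts = cfg.section("phantom")
    spec = default_phantom_spec(
        seed=cfg.seed,
        n=int(opts.get("n", 96)),
        spacing_mm=float(opts.get("spacing_mm", 0.13)),
    )
    scene, truth = generate_phantom(spec)
    mask = container_mask(spec)
    out = cfg.out_dir
    write_volume(out / "scene.nii.gz", scene.data, scene.grid)
    write_volume(out / "truth_labels.nii.gz", truth.labels, scene.grid)
    write_volume(out / "container_mask.nii.gz", mask.astype(np.uint8), scene.grid)
    truth.table.to_csv(out / "truth.csv", index=False)
    params = {"n": spec.grid.shape[0], "spacing_mm": spec.grid.spacing[0],
              "n_objects": truth.n_objects}
    return params, [out / "scene.nii.gz", out / "truth_labels.nii.gz",
                    out / "container_mask.nii.gz", out / "truth.csv"]


def _cmd_simulate(cfg: RunConfig):
    opts = cfg.section("simulate")
    scene_path = opts.get("scene", str(cfg.out_dir / "scene.nii.gz"))
    data, grid = read_volume(scene_path)
    scene = HRImage(grid, data)
    K = int(opts.get("views", 4))
    geo = default_study_geometry(n=grid.shape[0], sigma=float(opts.get("sigma", 0.05)))
    stacks, _ops = simulate_study(scene, K, geo, seed=cfg.seed)
    outputs = []
    for i, s in enumerate(stacks):
        p = cfg.out_dir / f"stack_{i:02d}.nii.gz"
        write_stack(p, s)
        outputs.append(p)
    gp = cfg.out_dir / "geometry.json"
    write_geometries(gp, stacks)
    outputs.append(gp)
    params = {"views": K, "sigma": geo.sigma, "angles_deg": [s.geometry.angle_deg for s in stacks]}
    return params, outputs


def _cmd_reconstruct(cfg: RunConfig):
    from .forward import ForwardOperator

    opts = cfg.section("reconstruct")
    stacks = _load_stacks(cfg, opts)
    n = int(opts.get("hr_n", stacks[0].geometry.shape[0]))
    spacing = float(opts.get("hr_spacing_mm", 0.13))
    grid = VoxelGrid.centered((n, n, n), spacing)
    operators = [ForwardOperator(grid, s.geometry, lr_origin=s.origin) for s in stacks]
    srr_cfg = SRRConfig(
        lam=opts.get("lam"),
        max_iter=int(opts.get("max_iter", 100)),
        tol=float(opts.get("tol", 1e-6)),
        init=opts.get("init", "mean-resampled"),
        bias_correct=bool(opts.get("bias_correct", False)),
        bias_scale_mm=float(opts.get("bias_scale_mm", 5.0)),
    )
    result = reconstruct(stacks, operators, srr_cfg)
    for it, res in enumerate(result.residual_history):
        log.debug("cg iteration %d relative residual %.3e", it, res)
    out = cfg.out_dir
    recon_path = out / opts.get("out_name", "recon.nii.gz")
    write_volume(recon_path, result.image.data, grid)
    hist_path = out / (recon_path.name.split(".")[0] + "_residuals.csv")
    hist_path.write_text(
        "iteration,relative_residual\n"
        + "\n".join(f"{i},{r}" for i, r in enumerate(result.residual_history))
    )
    outputs = [recon_path, hist_path]
    if result.gain_fields is not None and bool(opts.get("write_gains", False)):
        for i, (s, gain) in enumerate(zip(stacks, result.gain_fields)):
            gp = out / f"gain_{i:02d}.nii.gz"
            write_volume(gp, gain, s.grid())
            outputs.append(gp)
    params = {"lam": result.lam, "iterations": result.iterations,
              "K": len(stacks), "final_residual": result.residual_history[-1]}
    return params, outputs


def _cmd_voi(cfg: RunConfig):
    opts = cfg.section("voi")
    signal_path = opts.get("signal", str(cfg.out_dir / "scene.nii.gz"))
    data, grid = read_volume(signal_path)
    if "threshold" in opts:
        thr = float(opts["threshold"])
    elif "threshold_percentile" in opts:
        thr = float(np.percentile(data, float(opts["threshold_percentile"])))
    else:
        raise ValueError("voi stage needs 'threshold' or 'threshold_percentile'")
    vois = voi_from_signal(data, grid, thr, margin_mm=float(opts.get("margin_mm", 0.0)))
    path = cfg.out_dir / "vois.json"
    path.write_text(json.dumps([json.loads(v.to_json()) for v in vois], indent=2))
    return {"threshold": thr, "n_vois": len(vois)}, [path]


def _load_truth(cfg: RunConfig, opts: dict) -> PhantomTruth:
    import pandas as pd

    labels, _grid = read_volume(opts.get("truth_labels", str(cfg.out_dir / "truth_labels.nii.gz")))
    table = pd.read_csv(opts.get("truth_table", str(cfg.out_dir / "truth.csv")))
    return PhantomTruth(np.rint(labels).astype(int), table)


def _cmd_detect(cfg: RunConfig):
    opts = cfg.section("detect")
    vol_path = opts.get("volume", str(cfg.out_dir / "recon.nii.gz"))
    data, grid = read_volume(vol_path)
    params = _detection_params(opts)
    mask = None
    mask_path = opts.get("mask", str(cfg.out_dir / "container_mask.nii.gz"))
    if Path(mask_path).exists():
        mask = read_volume(mask_path)[0] > 0.5
    labels = bottom_hat_detect(data, params, mask)
    out = cfg.out_dir / "detections.nii.gz"
    write_volume(out, labels, grid)
    return {"volume": str(vol_path), "percentile": params.percentile,
            "n_detections": int(labels.max())}, [out]


def _cmd_evaluate(cfg: RunConfig):
    opts = cfg.section("evaluate")
    vol_path = opts.get("volume", str(cfg.out_dir / "recon.nii.gz"))
    data, _grid = read_volume(vol_path)
    params = _detection_params(opts)
    truth = _load_truth(cfg, opts)
    mask = None
    mask_path = opts.get("mask", str(cfg.out_dir / "container_mask.nii.gz"))
    if Path(mask_path).exists():
        mask = read_volume(mask_path)[0] > 0.5
    sweep, best_pct, best = threshold_sweep(data, truth, params, mask)
    cutoffs = list(opts.get("size_cutoffs", [0, 5, 10, 20, 40]))
    strat = size_stratified_fscore(data, truth, params, cutoffs, mask, detected=best.labels)
    out = cfg.out_dir
    sweep_path = out / "sweep.csv"
    strat_path = out / "size_fscore.csv"
    summary_path = out / "evaluate_summary.json"
    sweep.to_csv(sweep_path, index=False)
    strat.to_csv(strat_path, index=False)
    summary_path.write_text(json.dumps({
        "volume": str(vol_path),
        "best_percentile": best_pct,
        "precision": best.precision,
        "recall": best.recall,
        "f_score": best.f_score,
    }, indent=2))
    return {"best_percentile": best_pct, "f_score": best.f_score}, [
        sweep_path, strat_path, summary_path]


def _cmd_spectra(cfg: RunConfig):
    opts = cfg.section("spectra")
    vol_path = opts.get("volume", str(cfg.out_dir / "recon.nii.gz"))
    data, grid = read_volume(vol_path)
    axis = int(opts.get("slice_axis", 1))
    index = int(opts.get("slice_index", data.shape[axis] // 2))
    sl = [slice(None)] * 3
    sl[axis] = index
    plane = data[tuple(sl)]
    res = windowed_spectrum(plane, spacing_mm=grid.spacing[0],
                            cutoff_fraction=float(opts.get("cutoff_fraction", 0.5)))
    path = cfg.out_dir / "spectra.json"
    path.write_text(json.dumps({
        "volume": str(vol_path),
        "slice_axis": axis,
        "slice_index": index,
        "hf_fraction": res.hf_fraction,
        "cutoff_fraction": res.cutoff_fraction,
    }, indent=2))
    return {"hf_fraction": res.hf_fraction}, [path]
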