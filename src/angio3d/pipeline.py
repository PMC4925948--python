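"""End-to-end orchestration: images -> centrelines -> walls -> 3D model -> files."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enhance, walls as walls_mod
from .centerline import CenterlineCurve, extract_path, smooth_centerline, snap_to_skeleton
from .image import Image2D, load_image
from .recon import (ProjectionGeometry, build_tube, correspond_and_reconstruct,
                    estimate_radii, export_mesh, frenet_frames)

log = logging.getLogger("angio3d")


@dataclass
class SegmentSpec:
    """One vessel segment: user start/end points per view (row, col)."""

    name: str
    start: tuple  # ((row, col) view A, (row, col) view B)
    end: tuple


@dataclass
class RunConfig:
    images: list[str]
    geometry: list[dict]
    segments: list[SegmentSpec]
    output_dir: str = "angio3d_out"
    scales: tuple = enhance.DEFAULT_SCALES
    hysteresis_quantiles: tuple[float, float] = (0.80, 0.95)
    beta: float = walls_mod.DEFAULT_BETA
    epsilon: float = walls_mod.DEFAULT_EPSILON
    half_width: int = walls_mod.DEFAULT_HALF_WIDTH
    node_spacing: float = 1.0
    recon_tol_mm: float = 1e-3
    recon_max_iter: int = 20
    subdivisions: int = 16
    mesh_format: str = "stl"
    min_object_size: int = 64
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        images = raw.get("images", [])
        if len(images) != 2:
            raise ValueError("config must list exactly two view images")
        if base is not None:
            images = [str((base / p) if not os.path.isabs(p) else p) for p in images]
        for p in images:
            if not os.path.exists(p):
                raise ValueError(f"image not found: {p}")
        geometry = raw.get("geometry", [])
        if len(geometry) != 2:
            raise ValueError("config must provide geometry for both views")
        segs = [SegmentSpec(s["name"], tuple(map(tuple, s["start"])),
                            tuple(map(tuple, s["end"])))
                for s in raw.get("segments", [])]
        if not segs:
            raise ValueError("config must define at least one segment")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        opts = {k: v for k, v in raw.items()
                if k in known and k not in ("images", "geometry", "segments")}
        return cls(images=images, geometry=geometry, segments=segs, **opts)


def _extract_view_centerline(image: Image2D, cfg: RunConfig, start, end) -> CenterlineCurve:
    ves = enhance.vesselness_filter(image, cfg.scales)
    low, high = enhance.quantile_thresholds(ves, *cfg.hysteresis_quantiles)
    mask = enhance.hysteresis_threshold(ves, low, high)
    mask = enhance.clean_mask(mask, min_size=cfg.min_object_size)
    skel = enhance.skeletonize_and_label(mask)
    s = snap_to_skeleton(start, skel)
    e = snap_to_skeleton(end, skel)
    path = extract_path(skel, s, e)
    return smooth_centerline(path, skel, pixel_spacing_mm=image.pixel_spacing_mm)


def run_pipeline(config: RunConfig, seed: int = 0) -> dict:
    """Run all four stages for every segment; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = [load_image(p) for p in config.images]
    geoms = [ProjectionGeometry(**g) for g in config.geometry]
    params = walls_mod.DPParams(config.beta, config.epsilon)

    manifest = {
        "seed": seed,
        "images": [str(p) for p in config.images],
        "parameters": {
            "beta": config.beta, "epsilon": config.epsilon,
            "half_width": config.half_width, "node_spacing": config.node_spacing,
            "scales": list(config.scales),
            "recon_tol_mm": config.recon_tol_mm,
            "recon_max_iter": config.recon_max_iter,
            "subdivisions": config.subdivisions,
        },
        "segments": [],
    }
    written: list[Path] = []
    try:
        for seg in config.segments:
            log.info("segment %s: centreline extraction", seg.name)
            curves = []
            wall_pairs = []
            for v, img in enumerate(images):
                cl = _extract_view_centerline(img, config, seg.start[v], seg.end[v])
                curves.append(cl)
                wall_pairs.append(walls_mod.extract_vessel_walls(
                    img, cl, params, config.half_width, config.node_spacing))
            log.info("segment %s: 3D reconstruction", seg.name)
            model = correspond_and_reconstruct(
                curves[0], curves[1], geoms[0], geoms[1],
                tol_mm=config.recon_tol_mm, max_iter=config.recon_max_iter)
            estimate_radii(model, wall_pairs[0], wall_pairs[1], geoms[0], geoms[1])
            model.T, model.N, model.B, model.kappa, model.tau = frenet_frames(
                model.centerline3d)
            model.mesh = build_tube(model.centerline3d, model.radii,
                                    model.N, model.B, config.subdivisions)
            mesh_path = out / f"{seg.name}.{config.mesh_format}"
            export_mesh(model.mesh, mesh_path, config.mesh_format)
            written.append(mesh_path)
            csv_path = out / f"{seg.name}_centerline.csv"
            pd.DataFrame({
                "x_mm": model.centerline3d[:, 0],
                "y_mm": model.centerline3d[:, 1],
                "z_mm": model.centerline3d[:, 2],
                "radius_mm": model.radii,
                "kappa": model.kappa,
                "tau": model.tau,
            }).to_csv(csv_path, index=False, float_format="%.9g")
            written.append(csv_path)
            manifest["segments"].append({
                "name": seg.name,
                "mesh": str(mesh_path),
                "csv": str(csv_path),
                "n_points": int(len(model.centerline3d)),
                "recon_iterations": model.n_iterations,
                "mean_residual_mm": float(np.mean(model.residuals_mm)),
            })
    except Exception as exc:
        for p in written:  # partial outputs are cleaned on failure
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in segment processing: {exc}") from exc
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
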