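"""Seeded experiment orchestration and figure-style reporting.

An experiment is described by a YAML config (packaged defaults merged
with user overrides), validated before any compute, and produces a
manifest: every artifact (CSV table, TIFF/PNG image, HDF5 stack) listed
with its SHA-256 content hash, plus a line-delimited JSON log of stage
timings and parameter provenance.  Identical configs and seeds produce
hash-identical manifests.

Experiment kinds:

* ``ladder``      -- cell-count detection ladder (phantom detection limit)
* ``pcd``         -- band-dose versus mechanical-index sweep
* ``persistence`` -- signal persistence over a frame stack at no flow
* ``cbr``         -- contrast-to-background versus MI for both sequences
* ``ulm``         -- tumor-scene vascular mapping
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfgmod
from .acoustics import mechanical_index

__all__ = ["ExperimentConfig", "run_experiment", "report"]

_KNOWN_KINDS = ("ladder", "pcd", "persistence", "cbr", "ulm")


@dataclass
class ExperimentConfig:
    """Validated experiment description."""

    kind: str
    seeds: list[int]
    output_dir: Path
    params: dict = field(default_factory=dict)
    defaults: dict = field(default_factory=cfgmod.load_defaults)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        for block in ("experiment", "seeds", "output_dir"):
            if block not in raw:
                raise ValueError(f"config is missing required block {block!r}")
        kind = raw["experiment"]
        if kind not in _KNOWN_KINDS:
            raise ValueError(f"unknown experiment kind {kind!r}; expected one of {_KNOWN_KINDS}")
        seeds = raw["seeds"]
        if not isinstance(seeds, list) or not all(isinstance(s, int) for s in seeds) or not seeds:
            raise ValueError("seeds must be a non-empty list of integers (no wall-clock seeding)")
        defaults = cfgmod.load_defaults()
        for key in ("acoustics", "bubble", "detection", "pcd", "ulm"):
            if key in raw:
                defaults[key] = cfgmod._merge(defaults[key], raw[key])
        return cls(
            kind=kind,
            seeds=list(seeds),
            output_dir=Path(raw["output_dir"]),
            params=dict(raw.get("params", {})),
            defaults=defaults,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def log(self, **rec) -> None:
        self.records.append(rec)

    def flush(self) -> None:
        with open(self.path, "w") as f:
            for rec in self.records:
                f.write(json.dumps(rec, sort_keys=True) + "\n")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment; returns (and writes) its manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log = _Logger(out / "log.jsonl")
    log.log(stage="start", kind=config.kind, seeds=config.seeds, params=config.params)
    t0 = time.perf_counter()
    artifacts = _DISPATCH[config.kind](config, out, log)
    log.log(stage="done", elapsed_s=round(time.perf_counter() - t0, 3))
    log.flush()
    manifest = {
        "kind": config.kind,
        "seeds": config.seeds,
        "params": config.params,
        "artifacts": [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in sorted(artifacts)
        ],
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _run_ladder(config: ExperimentConfig, out: Path, log: _Logger) -> list[Path]:
    from .imaging import detection_experiment

    p = config.params
    ladder = p.get("ladder", [3.11e5, 3.11e4, 3.11e3, 3.11e2])
    table, min_count = detection_experiment(
        ladder,
        sequence=p.get("sequence", "ampi"),
        n_seeds=p.get("n_seeds", len(config.seeds)),
        mi=p.get("mi", 0.14),
        seed=config.seeds[0],
    )
    log.log(stage="ladder", min_detectable_count=min_count)
    path = out / "detection_ladder.csv"
    table.to_csv(path, index=False)
    summary = out / "detection_summary.csv"
    pd.DataFrame([{"min_detectable_count": min_count}]).to_csv(summary, index=False)
    return [path, summary]


def _run_pcd(config: ExperimentConfig, out: Path, log: _Logger) -> list[Path]:
    from .pcd import mi_sweep

    p = config.params
    bubble = cfgmod.default_phagocytosed_bubble(config.defaults)
    grid = p.get("mi_grid", [0.08, 0.14, 0.21, 0.34, 0.51, 0.68])
    df = mi_sweep(bubble, grid, seed=config.seeds[0])
    path = out / "dose_vs_mi.csv"
    df.to_csv(path, index=False)
    log.log(stage="pcd", n_mi=len(grid))
    return [path]


def _run_persistence(config: ExperimentConfig, out: Path, log: _Logger) -> list[Path]:
    from .imaging import FrameStack, channel_roi_mask, image_scene, signal_persistence
    from .scene import make_vessel_phantom

    p = config.params
    n_frames = p.get("n_frames", 20)
    ctx = cfgmod.imaging_context(config.defaults)
    scene = make_vessel_phantom(
        p.get("concentration", 3.11e5), 1.0, ctx, seed=config.seeds[0], count_mode="exact"
    )
    frames = [
        image_scene(scene, p.get("sequence", "bmode"), mi=p.get("mi", 0.14), seed=s)
        for s in range(n_frames)
    ]
    stack = FrameStack(frames=frames, timestamps=np.arange(n_frames, dtype=float))
    roi = channel_roi_mask(frames[0], scene.channel)
    curve, decline = signal_persistence(stack, roi)
    path = out / "persistence.csv"
    pd.DataFrame({"frame": np.arange(n_frames), "normalized_intensity": curve}).to_csv(
        path, index=False
    )
    log.log(stage="persistence", fractional_decline=decline)
    return [path]


def _run_cbr(config: ExperimentConfig, out: Path, log: _Logger) -> list[Path]:
    from .imaging import (
        channel_roi_mask,
        contrast_to_background_db,
        gel_background_mask,
        image_scene,
    )
    from .scene import make_vessel_phantom

    p = config.params
    ctx = cfgmod.imaging_context(config.defaults)
    rows = []
    for mi in p.get("mi_grid", [0.08, 0.14, 0.21]):
        for labeled, name in ((1.0, "labeled"), (0.0, "unlabeled")):
            for seed in config.seeds:
                scene = make_vessel_phantom(
                    p.get("concentration", 3.11e5), labeled, ctx, seed=seed, count_mode="exact"
                )
                for seq in ("bmode", "ampi"):
                    img = image_scene(scene, seq, mi=mi, seed=seed)
                    cbr = contrast_to_background_db(
                        img,
                        channel_roi_mask(img, scene.channel),
                        gel_background_mask(img, scene.channel),
                    )
                    rows.append(
                        {"mi": mi, "cells": name, "sequence": seq, "seed": seed, "cbr_db": cbr}
                    )
    df = pd.DataFrame(rows)
    path = out / "cbr_vs_mi.csv"
    df.to_csv(path, index=False)
    log.log(stage="cbr", n_rows=len(df))
    return [path]


def _run_ulm(config: ExperimentConfig, out: Path, log: _Logger) -> list[Path]:
    import tifffile

    from .scene import make_tumor_scene
    from .ulm import SVDFilterSpec, synthesize_flow_stack, vascular_map

    p = config.params
    u = config.defaults["ulm"]
    scene, lines = make_tumor_scene(
        n_vessels=p.get("n_vessels", 6),
        vessel_tortuosity=p.get("vessel_tortuosity", 0.3),
        periphery_bias=p.get("periphery_bias", 1.0),
        seed=config.seeds[0],
        bubbles_per_vessel=1,
        vessel_radius=p.get("vessel_radius", 100e-6),
    )
    stack = synthesize_flow_stack(
        scene,
        lines,
        n_frames=p.get("n_frames", 150),
        dt=p.get("dt", 0.01),
        transits_per_bubble=p.get("transits_per_bubble", 6),
        seed=config.seeds[0],
    )
    spec = SVDFilterSpec(low_fraction=u["low_fraction"], high_fraction=u["high_fraction"])
    vmap, locs = vascular_map(
        stack,
        spec,
        n_iterations=u["rl_iterations"],
        upsample=u["upsample"],
        smoothing_sigma=u["smoothing_sigma_px"],
    )
    map_path = out / "vascular_map.tiff"
    tifffile.imwrite(map_path, vmap.astype(np.float32))
    locs_path = out / "localizations.csv"
    x0, x1 = scene.x_limits
    z0, z1 = scene.z_limits
    nz = stack.shape[1] - 1
    nx = stack.shape[2] - 1
    pd.DataFrame(
        {
            "x_um": (locs[:, 1] / nx * (x1 - x0) + x0) * 1e6,
            "z_um": (locs[:, 0] / nz * (z1 - z0) + z0) * 1e6,
        }
    ).to_csv(locs_path, index=False)
    log.log(stage="ulm", n_localizations=int(len(locs)))
    return [map_path, locs_path]


_DISPATCH = {
    "ladder": _run_ladder,
    "pcd": _run_pcd,
    "persistence": _run_persistence,
    "cbr": _run_cbr,
    "ulm": _run_ulm,
}


def report(manifest: dict, output_dir) -> list[Path]:
    """Render summary panels (PNG) from an experiment manifest.

    Empty manifests produce an empty report and exit successfully.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    outputs: list[Path] = []
    for art in manifest.get("artifacts", []):
        path = out / art["path"]
        if path.suffix != ".csv" or not path.exists():
            continue
        df = pd.read_csv(path)
        if df.empty or df.shape[1] < 2:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        xcol = df.columns[0]
        for ycol in df.columns[1:]:
            if pd.api.types.is_numeric_dtype(df[ycol]):
                ax.plot(df[xcol], df[ycol], marker="o", label=ycol)
        ax.set_xlabel(xcol)
        ax.legend(fontsize=7)
        ax.set_title(path.stem.replace("_", " "))
        png = path.with_suffix(".png")
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        outputs.append(png)
    return outputs
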