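"""End-to-end run orchestration, reporting and manifests.

A run renders a synthetic slide, stitches and quality-controls the tiles,
runs the baseline detector, evaluates it against the simulator's ground
truth, profiles the eight anther size ranges and recommends the culture
range, and (optionally) summarizes a simulated doubled-haploid family.
Every artifact is written under one run directory with a manifest of
content hashes; a rerun from the same config and seed is bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .antherselect import (
    profile_to_frame,
    recommend_range,
    write_profile,
    write_recommendation,
)
from .detmetrics import evaluate
from .dhverify import (
    donor_het_positions,
    group_summary,
    simulate_family,
    summaries_to_frame,
)
from .geometry import AcquisitionGeometry
from .labelset import write_coco
from .simcell import MaturationProfileModel, SlideSimConfig, render_slide, sample_profile, tile_id
from .stagedetect import MorphologyDetector, RuleSet, default_ruleset, detect
from .scanproc import drop_empty, filter_unfocused, stitch


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    output_dir: str = "pollenscan_run"
    geometry: dict = field(default_factory=dict)  # AcquisitionGeometry kwargs
    sim: dict = field(default_factory=dict)  # SlideSimConfig kwargs (seed injected)
    focus_policy: str | float = "otsu"
    min_foreground: float = 0.001
    ruleset_path: str | None = None
    iou_threshold: float = 0.5
    profile_cells_per_range: float = 30000.0
    dh_family: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.output_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    geometry = AcquisitionGeometry(**config.geometry)
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SlideSimConfig(**sim_kwargs)
    if config.ruleset_path is not None:
        ruleset_file = Path(config.ruleset_path)
        if not ruleset_file.exists():
            raise FileNotFoundError(f"ruleset file not found: {ruleset_file}")
        ruleset = RuleSet.from_yaml(ruleset_file)
    else:
        ruleset = default_ruleset()

    # --- simulate ---------------------------------------------------------
    slide = render_slide(sim, geometry)
    for tile in slide.tiles:
        iio.imwrite(out / "images" / f"{tile_id(tile.grid_pos)}.png", tile.pixels)
    truth = [a for anns in slide.tile_annotations.values() for a in anns]
    write_coco(
        truth,
        out / "annotations.json",
        image_sizes={tid: (geometry.tile_px, geometry.tile_px) for tid in slide.tile_annotations},
    )
    with open(out / "sidecar.json", "w") as fh:
        json.dump(
            {
                "true_offsets": {tile_id(p): list(v) for p, v in slide.true_offsets.items()},
                "blur_flags": {tile_id(p): bool(v) for p, v in slide.blur_flags.items()},
                "seed": sim.seed,
            },
            fh,
            indent=1,
        )

    # --- stitch + QC ------------------------------------------------------
    macro = stitch(slide.tiles, sim.overlap_fraction, jitter_window_px=max(sim.jitter_px, 1) + 2)
    iio.imwrite(out / "macro.png", macro.pixels)
    kept, unfocused, focus_report = filter_unfocused(slide.tiles, config.focus_policy)
    kept, empty = drop_empty(kept, config.min_foreground)
    qc = {
        "registry": {tile_id(p): list(v) for p, v in macro.registry.items()},
        "stitch_warnings": macro.warnings,
        "focus_threshold": focus_report["threshold"],
        "focus_scores": {
            tile_id(t.grid_pos): s for t, s in zip(slide.tiles, focus_report["scores"])
        },
        "removed_unfocused": [tile_id(t.grid_pos) for t in unfocused],
        "removed_empty": [tile_id(t.grid_pos) for t in empty],
        "kept": [tile_id(t.grid_pos) for t in kept],
    }
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=1)

    # --- detect + evaluate on the QC-passing tiles ------------------------
    detector = MorphologyDetector(ruleset=ruleset, pixel_pitch=geometry.pixel_pitch)
    detections, det_rows, score_rows = {}, [], []
    for tile in kept:
        tid = tile_id(tile.grid_pos)
        dets = detect(tile.pixels, detector)
        detections[tid] = dets
        for d in dets:
            det_rows.append(
                {
                    "image_id": tid,
                    "category_id": d.top_class.value,
                    "bbox": [float(v) for v in d.bbox],
                    "score": d.confidence,
                }
            )
            score_rows.append({"image_id": tid, "bbox": [float(v) for v in d.bbox],
                               "scores": [float(s) for s in d.scores]})
    with open(out / "detections.json", "w") as fh:
        json.dump(det_rows, fh, indent=1)
    with open(out / "detection_scores.json", "w") as fh:
        json.dump(score_rows, fh, indent=1)

    kept_ids = {tile_id(t.grid_pos) for t in kept}
    eval_preds = [d for dets in detections.values() for d in dets]
    eval_truth = [a for tid in sorted(kept_ids) for a in slide.tile_annotations[tid]]
    result = evaluate(eval_preds, eval_truth, config.iou_threshold) if eval_truth else None
    if result is not None:
        result.to_json(out / "evaluation.json")
        result.to_frame().to_csv(out / "precision_table.csv", index=False)

    # --- anther-range profile + recommendation ----------------------------
    model = MaturationProfileModel(cells_per_range=config.profile_cells_per_range)
    profile = sample_profile(model, seed=config.seed + 1)
    write_profile(profile, out / "profile.csv")
    rec = recommend_range(profile)
    write_recommendation(rec, out / "recommendation.json")

    # --- doubled-haploid family check --------------------------------------
    if config.dh_family:
        fam = simulate_family(seed=config.seed + 2)
        positions, _ = donor_het_positions(fam, "donor")
        summaries, warn = group_summary(fam, positions)
        summaries_to_frame(summaries).to_csv(out / "het_summary.csv", index=False)

    render_report(out)
    _write_manifest(out, config)
    return out


def render_report(run_dir) -> Path:
    """Render the per-range stacked stage-count figure and report CSVs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    profile_csv = run_dir / "profile.csv"
    df = pd.read_csv(profile_csv)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    stage_cols = [c for c in df.columns if c not in ("range_label", "n_anthers")]
    if df[stage_cols].to_numpy().sum() == 0:
        ax.text(0.5, 0.5, "no cells detected", ha="center", va="center")
        ax.set_axis_off()
        fig.suptitle("Empty profile (warning)")
    else:
        bottom = np.zeros(len(df))
        for col in stage_cols:
            ax.bar(df["range_label"], df[col], bottom=bottom, label=col)
            bottom += df[col].to_numpy(float)
        ax.set_xlabel("anther size range")
        ax.set_ylabel("cells classified")
        ax.legend(title="stage", ncols=6, fontsize=8)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig_path = run_dir / "range_profile.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return fig_path


def _write_manifest(out: Path, config: RunConfig) -> None:
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
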