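"""Pipeline orchestration: configuration, stage execution, and reports.

A :class:`RunConfig` (YAML-serializable) selects stages and carries the
calibrations and stage parameters, all defaulting to the published
values (7.9/0.23 detection, 15-frame gate, 1.1 µm opening disk,
0.077 µm² filopodia gate, 100–350 voxel volume window, k = 5 neighbors,
8 px centroid dedupe, 135 µm adhesion window, 56 µm² intensity ROI,
padj < 0.05 and |log2FC| >= 1 DEG gates).  ``run_pipeline`` executes the
requested stages on synthetic inputs with known ground truth, writes
per-stage CSV/JSON artifacts, and returns a summary report; outputs are
deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry2d as m2d
from . import morphometry3d as m3d
from . import neighborhood as nbh
from . import regulatory_overlap as reg
from . import synthetic_data as syn
from . import tracking as trk

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "load_config", "save_config"]

ALL_STAGES = ("migration", "morphometry2d", "morphometry3d",
              "density", "enrichment")


@dataclass(frozen=True)
class RunConfig:
    """Serializable pipeline configuration (version 1 schema)."""

    schema_version: int = 1
    stages: tuple = ALL_STAGES
    seed: int = 0
    out_dir: str = "gastruquant_out"

    # calibrations
    pixel_size_um: float = 0.189
    frame_interval_min: float = 4.0
    voxel_size_um: tuple = m3d.DEFAULT_VOXEL_SIZE

    # migration stage
    persistence_group_a: float = 0.9
    persistence_group_b: float = 0.4
    n_embryos_per_group: int = 3
    n_tracks_per_embryo: int = 200
    n_steps: int = 120
    min_frames: int = 15

    # 2D morphometry stage
    n_star_cells: int = 5
    fa_total_target_um: float = 200.0

    # 3D morphometry stage
    flatness_ratios: tuple = (1.0, 1.5, 2.0, 3.0)

    # density stage
    n_density_embryos: int = 5
    density_rate_active: float = 0.005
    density_rate_inactive: float = 0.02
    knn_k: int = 5
    dedupe_px: float = 8.0
    border_margin_px: float = 8.0

    # enrichment stage
    n_genes: int = 1000
    n_peaks: int = 100
    n_deg: int = 150
    enrichment_factor: float = 3.0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("stages", "voxel_size_um", "flatness_ratios"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    data = asdict(config)
    for key in ("stages", "voxel_size_um", "flatness_ratios"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems; empty iff valid."""
    problems = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            problems.append(f"unknown stage {stage!r}")
    for name in ("pixel_size_um", "frame_interval_min"):
        if not getattr(config, name) > 0:
            problems.append(f"{name} must be positive")
    if any(v <= 0 for v in config.voxel_size_um):
        problems.append("voxel_size_um entries must be positive")
    for name in ("persistence_group_a", "persistence_group_b"):
        if not 0 <= getattr(config, name) <= 1:
            problems.append(f"{name} must lie in [0, 1]")
    for name in ("n_embryos_per_group", "n_tracks_per_embryo", "n_steps",
                 "min_frames", "n_star_cells", "n_density_embryos",
                 "n_genes", "n_peaks", "n_deg", "knn_k"):
        if getattr(config, name) < 1:
            problems.append(f"{name} must be >= 1")
    if config.enrichment_factor < 0:
        problems.append("enrichment_factor must be >= 0")
    if config.n_deg > config.n_genes:
        problems.append("n_deg cannot exceed n_genes")
    if config.n_peaks > config.n_genes:
        problems.append("n_peaks cannot exceed n_genes")
    return problems


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def _stage_migration(config: RunConfig, out: Path, seed: int) -> dict:
    params = trk.DetectionParams(
        pixel_size_um=config.pixel_size_um,
        frame_interval_min=config.frame_interval_min,
        min_frames=config.min_frames,
        midline_x_um=-1e9,  # synthetic arena has no midline; disable the cut
        midline_halfwidth_um=1e-9,
    )
    group_means = {}
    all_metrics = []
    for gi, p in enumerate((config.persistence_group_a,
                            config.persistence_group_b)):
        means = []
        for e in range(config.n_embryos_per_group):
            tracks = syn.simulate_persistent_tracks(syn.TrackSimParams(
                n_tracks=config.n_tracks_per_embryo, n_steps=config.n_steps,
                dt_min=config.frame_interval_min, persistence_p=p,
                seed=seed + 1000 * gi + e))
            metrics = [trk.compute_track_metrics(t, params) for t in tracks]
            metrics = trk.filter_tracks(metrics, params)
            df = trk.metrics_to_frame(metrics)
            df.insert(0, "group", "AB"[gi])
            df.insert(1, "embryo", e)
            all_metrics.append(df)
            means.append(float(df["persistence"].mean()))
        group_means["AB"[gi]] = means
    metrics_df = pd.concat(all_metrics, ignore_index=True)
    _write_csv(metrics_df, out / "migration_metrics.csv")
    report = trk.compare_groups(group_means["A"], group_means["B"])
    report["persistence_p"] = {"A": config.persistence_group_a,
                               "B": config.persistence_group_b}
    report["embryo_means"] = group_means
    return report


def _stage_morphometry2d(config: RunConfig, out: Path, seed: int) -> dict:
    rows = []
    for i in range(config.n_star_cells):
        cell, truth = syn.make_star_cell(n_spikes=4 + i, seed=seed + i)
        rows.append({
            "cell": i,
            "true_spikes": truth["n_above_gate"],
            "counted_filopodia": m2d.count_filopodia(cell),
            "compactness": m2d.compactness(cell),
            "area_um2": cell.area_um2,
        })
    cells_df = pd.DataFrame(rows)
    _write_csv(cells_df, out / "morphometry2d_cells.csv")

    # focal-adhesion pattern summing to the configured total length
    n_bars, total = 8, config.fa_total_target_um
    bar_len = total / n_bars
    segments = [((20.0, 12.0 + 15.0 * i), (20.0 + bar_len, 12.0 + 15.0 * i))
                for i in range(n_bars)]
    img, truth = syn.make_fa_pattern(segments)
    fa_len = m2d.total_fa_length(img > 0.5, 0.189, roi_side_um=135.0)
    return {
        "filopodia_exact": int((cells_df["true_spikes"]
                                == cells_df["counted_filopodia"]).sum()),
        "n_cells": len(cells_df),
        "mean_compactness": float(cells_df["compactness"].mean()),
        "fa_true_length_um": truth["total_length_um"],
        "fa_measured_length_um": fa_len,
    }


def _stage_morphometry3d(config: RunConfig, out: Path, seed: int) -> dict:
    rows = []
    for ratio in config.flatness_ratios:
        c = 1.5
        b = ratio * c
        a = max(b, 4.5)
        grid, truth = syn.make_ellipsoid_stack((a, b, c))
        # noise-free fixture: segment directly; the sigma=2 blur is for
        # noisy stacks and would anisotropically bias the axes
        labels = m3d.segment_nuclei_3d(grid, threshold=0.5)
        shapes = m3d.describe_labels(labels, grid.voxel_size_um)
        best = max(shapes, key=lambda s: s.volume_voxels)
        rows.append({
            "true_flatness": truth["flatness"],
            "measured_flatness": best.flatness,
            "sphericity": best.sphericity,
            "volume_um3": best.volume_um3,
        })
    df = pd.DataFrame(rows)
    _write_csv(df, out / "morphometry3d_nuclei.csv")
    rel_err = (df["measured_flatness"] - df["true_flatness"]).abs() \
        / df["true_flatness"]
    return {
        "n_nuclei": len(df),
        "max_flatness_rel_error": float(rel_err.max()),
        "flatness_table": df.to_dict("records"),
    }


def _stage_density(config: RunConfig, out: Path, seed: int) -> dict:
    records = {}
    for e in range(config.n_density_embryos):
        field, mask = syn.make_point_field(
            rate_per_um2_a=config.density_rate_active,
            rate_per_um2_b=config.density_rate_inactive,
            seed=seed + e)
        field = nbh.dedupe_centroids(field, config.dedupe_px)
        field = nbh.exclude_border(field, config.border_margin_px)
        records[e] = nbh.density_records(field, mask, k=config.knn_k)
    all_rec = pd.concat(
        [r.assign(embryo=e) for e, r in records.items()], ignore_index=True)
    _write_csv(all_rec, out / "density_records.csv")
    return nbh.compare_density(records)


def _stage_enrichment(config: RunConfig, out: Path, seed: int) -> dict:
    fx = syn.make_genome_fixture(
        n_genes=config.n_genes, n_peaks=config.n_peaks,
        enrichment_factor=config.enrichment_factor, n_deg=config.n_deg,
        seed=seed)
    assign = reg.assign_closest_genes(fx["peaks"], fx["genes"])
    _write_csv(assign, out / "peak_to_gene.csv")
    target = set(assign["gene_id"].dropna())
    deg = reg.filter_degs(fx["degs"], direction="down")
    report = reg.enrichment_test(deg, target, fx["universe"])
    report["enrichment_factor"] = config.enrichment_factor
    return report


_STAGE_FN = {
    "migration": _stage_migration,
    "morphometry2d": _stage_morphometry2d,
    "morphometry3d": _stage_morphometry3d,
    "density": _stage_density,
    "enrichment": _stage_enrichment,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write artifacts + summary JSON."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    for stage in config.stages:
        report["stages"][stage] = _STAGE_FN[stage](config, out, config.seed)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
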