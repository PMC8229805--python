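"""Shared I/O, run configuration and the reproducible-run orchestrator.

Images move as single-plane 8/16-bit grayscale TIFFs; a run is described
by a YAML :class:`RunConfig`, executes deterministically from its seeds,
and leaves behind its resolved config plus a :class:`RunManifest` with
input/config hashes and every warning emitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .pipeline import PipelineConfig, analyze, load_rois, percent_change, stats_frame, stitch_tiles, summarize
from .synthetic import (
    CONDITIONS,
    MonolayerSpec,
    generate_channel,
    write_roi_txt,
    write_tiles,
    write_truth,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_image",
    "write_image",
    "run_pipeline",
    "contrast_recovery_experiment",
]

logger = logging.getLogger("cavigap")


def read_image(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Read a grayscale TIFF losslessly.

    Multi-channel files require an explicit ``channel`` index; 8- and
    16-bit values are returned untouched (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path}: image has {arr.shape[-1] if arr.shape[-1] < 5 else arr.shape[0]} "
                "channels; pass an explicit channel index"
            )
        arr = arr[..., channel] if arr.shape[-1] < 5 else arr[channel]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, got shape {arr.shape}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D uint8/uint16 array as TIFF (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.dtype not in (np.uint8, np.uint16):
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img)
    return path


_CONFIG_FIELDS: dict[str, object] = {
    "pixel_size_um": 0.65,
    "threshold_method": "otsu",
    "fixed_cutoff": None,
    "equalize_method": "stretch",
    "connectivity": 2,
    "min_blob_area_px": 4,
    "invert": False,
    "perimeter_method": "contour",
    "histogram_bins": 12,
    "seed": 0,
    "conditions": ["CTRL", "US", "USMB"],
    "field_px": 1024,
    "n_cells": 150,
    "grid": [2, 2],
    "out_dir": "cavigap_run",
}


@dataclass
class RunConfig:
    """Fully resolved run configuration (every field has a default)."""

    pixel_size_um: float = 0.65
    threshold_method: str = "otsu"
    fixed_cutoff: float | None = None
    equalize_method: str = "stretch"
    connectivity: int = 2
    min_blob_area_px: int = 4
    invert: bool = False
    perimeter_method: str = "contour"
    histogram_bins: int = 12
    seed: int = 0
    conditions: list[str] = field(default_factory=lambda: ["CTRL", "US", "USMB"])
    field_px: int = 1024
    n_cells: int = 150
    grid: list[int] = field(default_factory=lambda: [2, 2])
    out_dir: str = "cavigap_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        unknown = sorted(set(raw) - set(_CONFIG_FIELDS))
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {unknown}; valid keys: {sorted(_CONFIG_FIELDS)}"
            )
        return cls(**raw)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            pixel_size_um=self.pixel_size_um,
            threshold_method=self.threshold_method,
            fixed_cutoff=self.fixed_cutoff,
            equalize_method=self.equalize_method,
            connectivity=self.connectivity,
            min_blob_area_px=self.min_blob_area_px,
            invert=self.invert,
            perimeter_method=self.perimeter_method,
            histogram_bins=self.histogram_bins,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


@dataclass
class RunManifest:
    """Provenance record written next to a run's outputs."""

    tool_version: str
    started: str
    finished: str
    config_hash: str
    input_hashes: dict[str, str]
    output_hashes: dict[str, str]
    warnings: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def contrast_recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    field_px: int = 1024,
    n_cells: int = 150,
    conditions: tuple[str, ...] = ("CTRL", "US", "USMB"),
    grid: tuple[int, int] = (2, 2),
    min_recovery_area_px: int = 50,
    config: PipelineConfig | None = None,
) -> dict:
    """Replicated synthetic channels through the full pipeline.

    For each replicate seed, one cell mosaic is generated and each
    condition draws its own gap configuration on it; the channel is tiled
    with noise, stitched, and analysed on the truth ROIs.  Totals are
    pooled across seeds before taking percent change against the control,
    which estimates the programmed count-multiplier contrast.

    Returns a dict with pooled totals, percent changes, the pooled
    per-gap relative recovery errors for gaps of at least
    ``min_recovery_area_px`` rendered pixels, and bookkeeping counts.
    """
    from .synthetic import insert_gaps, render_tiles  # local: keeps module top light
    from .synthetic import generate_monolayer
    from .pipeline import RoiSpec

    pcfg = config if config is not None else PipelineConfig()
    totals = {c: 0.0 for c in conditions}
    counts = {c: 0 for c in conditions}
    rel_errors: list[float] = []
    missed = 0
    for i in range(n_seeds):
        seed = (base_seed + 7919 * i) % (2**31)
        spec = MonolayerSpec(field_width_px=field_px, field_height_px=field_px,
                             n_cells=n_cells, seed=seed)
        image, label_map = generate_monolayer(spec)
        for cond_label in conditions:
            cond = CONDITIONS[cond_label]
            img, truth = insert_gaps(
                image, label_map, cond, seed=seed,
                pixel_size_um=spec.pixel_size_um, intensity_gap=spec.intensity_gap,
            )
            tiles = render_tiles(
                img, grid[0], grid[1], overlap_fraction=0.2,
                noise_gaussian_sd=spec.noise_gaussian_sd,
                noise_poisson_scale=spec.noise_poisson_scale,
                seed=seed, pixel_size_um=spec.pixel_size_um,
            )
            stitched = stitch_tiles(tiles)
            rois = [
                RoiSpec(j + 1, int(r.roi_x), int(r.roi_y), int(r.roi_w), int(r.roi_h))
                for j, r in truth.records.iterrows()
            ]
            table = analyze(stitched, rois, pcfg)
            stats = summarize(table, cond_label)
            totals[cond_label] += stats.total_area_um2
            counts[cond_label] += stats.n_gaps
            missed += int((~table["found"]).sum())
            rec = truth.records.reset_index(drop=True)
            big = rec["area_px"].to_numpy() >= min_recovery_area_px
            got = table["area_px"].to_numpy(float)
            true_px = rec["area_px"].to_numpy(float)
            ok = big & np.isfinite(got)
            rel_errors.extend((np.abs(got[ok] - true_px[ok]) / true_px[ok]).tolist())

    ctrl = conditions[0]
    percent_changes = {
        c: 100.0 * (totals[c] - totals[ctrl]) / totals[ctrl] for c in conditions if c != ctrl
    }
    rel = np.asarray(rel_errors)
    return {
        "n_seeds": n_seeds,
        "totals_um2": totals,
        "gap_counts": counts,
        "missed_rois": missed,
        "percent_change": percent_changes,
        "recovery_n_gaps": int(rel.size),
        "recovery_max_rel_error": float(rel.max()) if rel.size else float("nan"),
        "recovery_mean_rel_error": float(rel.mean()) if rel.size else float("nan"),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """End-to-end demo run: synthesise each condition, stitch, analyse,
    aggregate, and report percent change vs the control.

    Every stage logs its decisions; all warnings raised during the run
    are captured into the manifest.  Outputs (per condition): tiles,
    stitched TIFF, truth/ROI files, per-gap CSV, histogram CSV; plus a
    cross-condition ``stats.csv``, the resolved config and the manifest.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    captured: list[str] = []
    input_hashes: dict[str, str] = {}
    output_hashes: dict[str, str] = {}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        pcfg = config.pipeline_config()
        stats_by_cond = {}
        for cond_label in config.conditions:
            if cond_label not in CONDITIONS:
                raise ValueError(f"stage synthetic: unknown condition {cond_label!r}; valid: {sorted(CONDITIONS)}")
            cond = CONDITIONS[cond_label]
            spec = MonolayerSpec(
                field_width_px=config.field_px,
                field_height_px=config.field_px,
                n_cells=config.n_cells,
                pixel_size_um=config.pixel_size_um,
                seed=config.seed,
            )
            logger.info("generating condition %s (seed %d)", cond_label, config.seed)
            image, truth, tiles = generate_channel(spec, cond, grid=tuple(config.grid))
            cdir = out / cond_label
            write_tiles(tiles, cdir / "tiles")
            truth_csv = write_truth(truth, cdir / "truth.csv")
            roi_txt = write_roi_txt(truth, cdir / "rois.txt")
            input_hashes[str(roi_txt.relative_to(out))] = _sha256(roi_txt)

            stitched = stitch_tiles(tiles)
            stitched_path = write_image(stitched, cdir / "stitched.tif")
            rois = load_rois(roi_txt)
            table = analyze(stitched, rois, pcfg)
            table_path = cdir / "per_gap.csv"
            table.to_csv(table_path, index=False)
            st = summarize(table, cond_label, n_bins=config.histogram_bins)
            hist_path = cdir / "histogram.csv"
            stats_frame(st).to_csv(hist_path, index=False)
            stats_by_cond[cond_label] = st
            for p in (truth_csv, stitched_path, table_path, hist_path):
                output_hashes[str(p.relative_to(out))] = _sha256(p)

        rows = []
        ctrl = stats_by_cond.get("CTRL")
        for label, st in stats_by_cond.items():
            pc = percent_change(st, ctrl) if (ctrl is not None and label != "CTRL") else 0.0
            rows.append(
                {
                    "condition": label,
                    "n_gaps": st.n_gaps,
                    "total_area_um2": st.total_area_um2,
                    "percent_change_vs_ctrl": pc,
                }
            )
        import pandas as pd

        stats_path = out / "stats.csv"
        pd.DataFrame(rows).to_csv(stats_path, index=False)
        output_hashes["stats.csv"] = _sha256(stats_path)
        captured = [str(w.message) for w in wlist]

    cfg_path = config.to_yaml(out / "config.resolved.yaml")
    manifest = RunManifest(
        tool_version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        config_hash=_sha256(cfg_path),
        input_hashes=input_hashes,
        output_hashes=output_hashes,
        warnings=captured,
    )
    manifest.to_json(out / "manifest.json")
    for msg in captured:
        logger.warning("run warning: %s", msg)
    return manifest
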