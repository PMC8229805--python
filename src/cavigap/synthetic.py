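"""Synthetic endothelial-monolayer fluorescence mosaics with ground truth.

The generator emulates the statistical structure of a junction-stained
confluent endothelial monolayer imaged in a perfused microchannel:

* a polygonal (anisotropic Voronoi) cell mosaic, stretched streamwise to
  mimic flow-aligned cell elongation, with bright ridge lines along the
  cell-cell junctions;
* interendothelial gaps rendered as bright elliptical-irregular blobs
  centred on junction ridges, with a Poisson-distributed count and a
  log-normal per-gap area distribution; an ``effect_multiplier`` scales
  the expected count relative to the control condition so programmed
  contrasts (e.g. 4.6x for ultrasound + microbubbles) are known exactly;
* overlapping noisy image tiles cut from the field (Poisson shot noise
  plus Gaussian read noise), the unit of stitching.

All randomness flows from one master seed through named substreams, so
identical specs give bit-identical images, tiles and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, footprint_rectangle
from skimage.segmentation import find_boundaries

__all__ = [
    "MonolayerSpec",
    "ConditionSpec",
    "GapTruth",
    "TileSet",
    "CONDITIONS",
    "generate_monolayer",
    "insert_gaps",
    "render_tiles",
    "write_tiles",
    "write_truth",
    "write_roi_txt",
    "generate_channel",
]

MAX_GRAY = 65535

# Programmed study conditions: expected control gap count, log-normal
# per-gap area (um^2), and count multipliers matching the +130% / +360%
# contrasts of ultrasound alone and ultrasound + microbubbles.
CONDITIONS: dict[str, "ConditionSpec"]


@dataclass(frozen=True)
class MonolayerSpec:
    """Geometry, optics and noise of one synthetic channel field."""

    field_width_px: int = 1024
    field_height_px: int = 1024
    n_cells: int = 150
    pixel_size_um: float = 0.65
    junction_width_px: int = 3
    cell_elongation: float = 1.6  # streamwise (x) anisotropy, >= 1
    intensity_background: int = 3000
    intensity_junction: int = 9000
    intensity_gap: int = 40000
    noise_gaussian_sd: float = 800.0
    noise_poisson_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.field_width_px, self.field_height_px) < 64:
            raise ValueError("field dimensions must be >= 64 px")
        if not (0 <= self.intensity_background < self.intensity_junction < self.intensity_gap <= MAX_GRAY):
            raise ValueError("require intensity_gap > intensity_junction > intensity_background in [0, 65535]")
        if self.cell_elongation < 1:
            raise ValueError("cell_elongation must be >= 1")
        if self.junction_width_px < 1:
            raise ValueError("junction_width_px must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        mean_area = self.field_width_px * self.field_height_px / self.n_cells
        if mean_area < 25.0:
            raise ValueError(
                f"n_cells={self.n_cells} too large for a "
                f"{self.field_width_px}x{self.field_height_px} field "
                f"(mean cell area {mean_area:.1f} px^2 < 25 px^2)"
            )


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the gap-opening contrast."""

    label: str = "CTRL"
    n_gaps_mean: float = 60.0
    gap_area_logmean_um2: float = math.log(42.0)
    gap_area_logsd: float = 0.5
    effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_gaps_mean < 0:
            raise ValueError("n_gaps_mean must be >= 0")
        for name in ("gap_area_logsd", "effect_multiplier"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        if not math.isfinite(self.gap_area_logmean_um2):
            raise ValueError("gap_area_logmean_um2 must be finite")


CONDITIONS = {
    "CTRL": ConditionSpec("CTRL", effect_multiplier=1.0),
    "US": ConditionSpec("US", effect_multiplier=2.3),
    "USMB": ConditionSpec("USMB", effect_multiplier=4.6),
}


@dataclass
class GapTruth:
    """Ground-truth gap records for one generated field."""

    records: pd.DataFrame  # gap_id, centroid_x, centroid_y, area_px, area_um2, roi_x, roi_y, roi_w, roi_h
    condition: str
    seed: int
    requested_n: int
    placed_n: int

    @property
    def truncated(self) -> bool:
        """True when fewer gaps fitted than were drawn."""
        return self.placed_n < self.requested_n

    @property
    def total_area_um2(self) -> float:
        return float(self.records["area_um2"].sum())

    @property
    def total_area_px(self) -> int:
        return int(self.records["area_px"].sum())


@dataclass
class TileSet:
    """Row-major grid of overlapping tiles cut from one field."""

    tiles: list[list[np.ndarray]]
    overlap_fraction: float
    true_offsets_px: list[list[tuple[int, int]]]  # (row, col) placement of each tile
    pixel_size_um: float

    @property
    def grid_shape(self) -> tuple[int, int]:
        return len(self.tiles), len(self.tiles[0])

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0][0].shape


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream derived from the master seed (stable across runs)."""
    child = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "little") % (2**63)])
    return np.random.default_rng(child)


def _seed_points(spec: MonolayerSpec) -> np.ndarray:
    """Poisson-disc-like cell centres via dart throwing with a minimum
    spacing of half the mean cell pitch (in the isotropised frame)."""
    rng = _rng(spec.seed, "cells")
    w, h = spec.field_width_px, spec.field_height_px
    pitch = math.sqrt(w * h / spec.n_cells)
    min_d = 0.5 * pitch
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < spec.n_cells and attempts < 200 * spec.n_cells:
        attempts += 1
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        # spacing enforced in the elongation-compressed frame
        ok = all((((x - px) / spec.cell_elongation) ** 2 + (y - py) ** 2) >= min_d**2 for px, py in pts)
        if ok:
            pts.append((x, y))
    while len(pts) < spec.n_cells:  # fill remainder unconditionally
        pts.append((rng.uniform(0, w), rng.uniform(0, h)))
    return np.asarray(pts)


def generate_monolayer(spec: MonolayerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the noiseless monolayer field and its cell label map.

    Returns ``(image, cell_label_map)`` where the image is uint16 with
    junction ridges at ``intensity_junction`` over a uniform background,
    and the label map assigns each pixel its cell id (1..n_cells) or 0 on
    a junction ridge.  Cells are anisotropic Voronoi regions of dart-thrown
    seed points: distances are measured with the streamwise coordinate
    compressed by ``cell_elongation``, which stretches cells along x.
    """
    w, h = spec.field_width_px, spec.field_height_px
    pts = _seed_points(spec)
    # nearest-seed assignment in the compressed frame == anisotropic Voronoi
    scaled = np.column_stack([pts[:, 0] / spec.cell_elongation, pts[:, 1]])
    tree = cKDTree(scaled)
    yy, xx = np.mgrid[0:h, 0:w]
    query = np.column_stack([(xx.ravel() / spec.cell_elongation), yy.ravel()])
    _, idx = tree.query(query, workers=-1)
    labels = (idx + 1).reshape(h, w).astype(np.int32)

    if spec.n_cells > 1:
        ridges = find_boundaries(labels, mode="thick")
        if spec.junction_width_px > 2:
            k = spec.junction_width_px
            ridges = dilation(ridges, footprint_rectangle((k, k)))
    else:
        ridges = np.zeros((h, w), bool)

    image = np.full((h, w), spec.intensity_background, np.uint16)
    image[ridges] = spec.intensity_junction
    label_map = labels.copy()
    label_map[ridges] = 0
    return image, label_map


def insert_gaps(
    image: np.ndarray,
    cell_label_map: np.ndarray,
    condition: ConditionSpec,
    seed: int,
    pixel_size_um: float = 0.65,
    intensity_gap: int = 40000,
    roi_pad_px: int = 3,
    max_tries_per_gap: int = 60,
) -> tuple[np.ndarray, GapTruth]:
    """Draw bright gap blobs on junction ridges; return image + truth.

    The gap count is Poisson(n_gaps_mean * effect_multiplier); per-gap
    target areas are log-normal in um^2.  Each gap is an irregular ellipse
    (random orientation and 0.45-1 axis ratio) centred on a ridge pixel;
    gaps are rejection-sampled so they never overlap one another.  The
    truth table records the *rendered* pixel count, so segmentation can be
    scored against what is actually in the image.
    """
    rng = _rng(seed, f"gaps:{condition.label}")
    h, w = image.shape
    n_req = int(rng.poisson(condition.n_gaps_mean * condition.effect_multiplier))
    out = image.copy()
    occupied = np.zeros_like(image, bool)
    ridge = cell_label_map == 0
    ridge_idx = np.flatnonzero(ridge)
    rows_all, cols_all = np.unravel_index(ridge_idx, image.shape) if ridge_idx.size else ((), ())

    recs = []
    placed = 0
    for gid in range(n_req):
        if ridge_idx.size == 0:
            break
        area_um2 = float(rng.lognormal(condition.gap_area_logmean_um2, condition.gap_area_logsd))
        area_px_target = max(4.0, area_um2 / pixel_size_um**2)
        for _ in range(max_tries_per_gap):
            k = rng.integers(0, ridge_idx.size)
            cy, cx = int(rows_all[k]), int(cols_all[k])
            ratio = rng.uniform(0.45, 1.0)
            theta = rng.uniform(0.0, math.pi)
            # semi-axes a >= b with pi*a*b = target area
            a = math.sqrt(area_px_target / (math.pi * ratio))
            b = a * ratio
            # mild boundary irregularity: jitter the axes a few percent
            a *= rng.uniform(0.92, 1.08)
            b *= rng.uniform(0.92, 1.08)
            rr, cc = draw_ellipse(cy, cx, b, a, shape=image.shape, rotation=theta)
            if rr.size == 0:
                continue
            # 2 px clearance so neighbouring gaps never become 8-connected
            rr_m, cc_m = draw_ellipse(cy, cx, b + 2, a + 2, shape=image.shape, rotation=theta)
            if occupied[rr_m, cc_m].any():
                continue
            out[rr, cc] = intensity_gap
            occupied[rr, cc] = True
            area_px = int(rr.size)
            y0, y1 = int(rr.min()), int(rr.max())
            x0, x1 = int(cc.min()), int(cc.max())
            rx = max(0, x0 - roi_pad_px)
            ry = max(0, y0 - roi_pad_px)
            rw = min(w, x1 + 1 + roi_pad_px) - rx
            rh = min(h, y1 + 1 + roi_pad_px) - ry
            recs.append(
                {
                    "gap_id": placed,
                    "condition": condition.label,
                    "centroid_x": float(cc.mean()),
                    "centroid_y": float(rr.mean()),
                    "area_px": area_px,
                    "area_um2": area_px * pixel_size_um**2,
                    "roi_x": rx,
                    "roi_y": ry,
                    "roi_w": rw,
                    "roi_h": rh,
                }
            )
            placed += 1
            break
    columns = [
        "gap_id", "condition", "centroid_x", "centroid_y",
        "area_px", "area_um2", "roi_x", "roi_y", "roi_w", "roi_h",
    ]
    df = pd.DataFrame(recs, columns=columns)
    truth = GapTruth(records=df, condition=condition.label, seed=seed, requested_n=n_req, placed_n=placed)
    return out, truth


def render_tiles(
    image: np.ndarray,
    grid_rows: int,
    grid_cols: int,
    overlap_fraction: float,
    noise_gaussian_sd: float = 0.0,
    noise_poisson_scale: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.65,
) -> TileSet:
    """Cut the field into an overlapping grid of noisy tiles.

    The tile size is chosen so adjacent tiles share at least
    ``overlap_fraction`` of their width/height and the grid covers the
    field exactly; true placements are recorded so reassembly is exact
    (before noise).  Shot noise: pixel ~ Poisson(I*s)/s with
    s = ``noise_poisson_scale`` (variance I/s); read noise: additive
    Gaussian.  With both noise parameters zero the tiles are plain crops.
    """
    if not (0.0 < overlap_fraction <= 0.5):
        raise ValueError(f"overlap_fraction must lie in (0, 0.5], got {overlap_fraction}")
    h, w = image.shape
    rng = _rng(seed, "tilenoise")

    def _layout(extent: int, n: int) -> tuple[int, list[int]]:
        if n == 1:
            return extent, [0]
        size = math.ceil(extent / (n - (n - 1) * overlap_fraction))
        size = min(size, extent)
        offs = [round(i * (extent - size) / (n - 1)) for i in range(n)]
        return size, offs

    th, offs_r = _layout(h, grid_rows)
    tw, offs_c = _layout(w, grid_cols)

    tiles: list[list[np.ndarray]] = []
    offsets: list[list[tuple[int, int]]] = []
    noisy = noise_gaussian_sd > 0 or noise_poisson_scale > 0
    for r in range(grid_rows):
        row_tiles, row_offs = [], []
        for c in range(grid_cols):
            oy, ox = offs_r[r], offs_c[c]
            crop = image[oy : oy + th, ox : ox + tw].astype(np.float64)
            if noisy:
                if noise_poisson_scale > 0:
                    crop = rng.poisson(crop * noise_poisson_scale) / noise_poisson_scale
                if noise_gaussian_sd > 0:
                    crop = crop + rng.normal(0.0, noise_gaussian_sd, crop.shape)
                tile = np.clip(np.rint(crop), 0, MAX_GRAY).astype(np.uint16)
            else:
                tile = image[oy : oy + th, ox : ox + tw].copy()
            row_tiles.append(tile)
            row_offs.append((oy, ox))
        tiles.append(row_tiles)
        offsets.append(row_offs)
    return TileSet(tiles=tiles, overlap_fraction=overlap_fraction, true_offsets_px=offsets, pixel_size_um=pixel_size_um)


def write_tiles(tileset: TileSet, out_dir: str | Path) -> list[Path]:
    """Write tiles as 16-bit grayscale TIFFs named ``tile_r{R}_c{C}.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, row in enumerate(tileset.tiles):
        for c, tile in enumerate(row):
            p = out_dir / f"tile_r{r}_c{c}.tif"
            tifffile.imwrite(p, np.asarray(tile, np.uint16))
            paths.append(p)
    return paths


def write_truth(truth: GapTruth, path: str | Path) -> Path:
    """Ground-truth CSV: one row per gap, areas in px and um^2."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.records.to_csv(path, index=False)
    return path


def write_roi_txt(truth: GapTruth, path: str | Path) -> Path:
    """Emit the truth ROIs in the pipeline's TXT dialect (x y w h)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# ROIs for condition {truth.condition}, seed {truth.seed} (x y width height)"]
    for _, row in truth.records.iterrows():
        lines.append(f"{int(row.roi_x)} {int(row.roi_y)} {int(row.roi_w)} {int(row.roi_h)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def generate_channel(
    spec: MonolayerSpec,
    condition: ConditionSpec,
    grid: tuple[int, int] = (2, 2),
) -> tuple[np.ndarray, GapTruth, TileSet]:
    """Convenience: monolayer + gaps + noisy tiles for one condition.

    The gap substream is derived from the spec seed and the condition
    label, so CTRL/US/USMB channels of the same seed share the same cell
    mosaic but draw independent gap configurations.
    """
    image, label_map = generate_monolayer(spec)
    image, truth = insert_gaps(
        image,
        label_map,
        condition,
        seed=spec.seed,
        pixel_size_um=spec.pixel_size_um,
        intensity_gap=spec.intensity_gap,
    )
    tileset = render_tiles(
        image,
        grid[0],
        grid[1],
        overlap_fraction=0.2,
        noise_gaussian_sd=spec.noise_gaussian_sd,
        noise_poisson_scale=spec.noise_poisson_scale,
        seed=spec.seed,
        pixel_size_um=spec.pixel_size_um,
    )
    return image, truth, tileset
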