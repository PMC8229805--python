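"""Interendothelial gap segmentation and statistics.

End-to-end quantification of junction openings in stitched fluorescence
mosaics of an endothelial monolayer:

1. ``stitch_tiles`` — translation registration of an overlapping tile
   grid (phase correlation on the overlap strips, nominal-grid fallback)
   and linear-feather blending into one mosaic;
2. ``load_rois`` — rectangular regions of interest, one per candidate
   gap, from a plain-text file (``x y width height``, ``#`` comments);
3. per ROI: ``equalize`` (contrast normalisation) → ``binarize``
   (Otsu or fixed cut-off; pixels above the cut-off are gap signal) →
   ``label_blobs`` (8-connected components) → ``select_central_blob``
   (the component nearest the ROI centre is the gap) → ``measure``
   (area, perimeter, shape factor in physical units);
4. ``summarize`` / ``percent_change`` — per-condition totals, area
   histograms and the contrast against the untreated control.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .synthetic import MAX_GRAY, TileSet

__all__ = [
    "RoiSpec",
    "Blob",
    "GapMeasure",
    "GapStats",
    "PipelineConfig",
    "stitch_tiles",
    "load_rois",
    "equalize",
    "binarize",
    "label_blobs",
    "select_central_blob",
    "measure",
    "analyze",
    "summarize",
    "percent_change",
]

logger = logging.getLogger("cavigap")

PER_GAP_COLUMNS = [
    "roi_id", "found", "area_px", "area_um2",
    "perimeter_um", "shape_factor", "centroid_x", "centroid_y",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangle in stitched-image coordinates (0-based, x=column)."""

    roi_id: int
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError(f"ROI {self.roi_id}: width and height must be >= 3")

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) geometric centre of the rectangle, pixel-centre frame."""
        return self.y0 + (self.height - 1) / 2.0, self.x0 + (self.width - 1) / 2.0


@dataclass
class Blob:
    """One 8-connected component of a binary mask (ROI frame)."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]
    area_px: int
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (exclusive)


@dataclass(frozen=True)
class GapMeasure:
    """Physical geometry of one identified gap."""

    roi_id: int
    area_px: int
    area_um2: float
    perimeter_um: float
    shape_factor: float  # 4 pi A / P^2; ~1 for discs, -> 0 for filaments
    centroid: tuple[float, float]  # (row, col) in stitched-image coordinates


@dataclass
class GapStats:
    """Per-condition aggregate of the measured gaps."""

    condition: str
    n_gaps: int
    total_area_um2: float
    bin_edges: np.ndarray
    counts: np.ndarray
    table: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the per-ROI analysis."""

    pixel_size_um: float = 0.65
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_cutoff: float | None = None
    equalize_method: Literal["stretch", "hist"] = "stretch"
    connectivity: int = 2  # skimage convention: 2 == 8-connected
    min_blob_area_px: int = 4
    invert: bool = False  # set for stains where gaps are the darkest class
    perimeter_method: Literal["contour", "edge_count"] = "contour"
    histogram_bins: int = 12


# --------------------------------------------------------------------------
# stitching
# --------------------------------------------------------------------------

def _pair_offset(
    ref: np.ndarray,
    mov: np.ndarray,
    nominal: tuple[int, int],
    axis: int,
    min_confidence: float,
) -> tuple[tuple[int, int], bool]:
    """Relative (row, col) offset of ``mov`` w.r.t. ``ref`` along one axis.

    Phase correlation runs on the nominal overlap strips; the residual
    shift corrects the nominal offset.  A normalised correlation of the
    aligned strips below ``min_confidence`` falls back to the nominal
    grid offset.
    """
    h, w = ref.shape
    dy, dx = nominal
    if axis == 1:  # mov is the right neighbour
        strip_ref = ref[:, dx:]
        strip_mov = mov[:, : w - dx]
    else:  # mov is the bottom neighbour
        strip_ref = ref[dy:, :]
        strip_mov = mov[: h - dy, :]
    if strip_ref.size == 0 or strip_ref.std() == 0 or strip_mov.std() == 0:
        warnings.warn(
            f"stitch: featureless overlap, using nominal offset {nominal}", stacklevel=3
        )
        logger.warning("stitch fallback to nominal offset %s (featureless overlap)", nominal)
        return nominal, False
    shift, _, _ = phase_cross_correlation(
        strip_ref.astype(np.float64), strip_mov.astype(np.float64), normalization=None
    )
    sy, sx = int(round(shift[0])), int(round(shift[1]))
    est = (dy + sy, dx + sx) if axis == 1 else (dy + sy, dx + sx)
    # confidence: normalised correlation of the overlap re-aligned at est
    conf = _aligned_correlation(ref, mov, est)
    if conf < min_confidence:
        warnings.warn(
            f"stitch: low registration confidence ({conf:.2f}); using nominal offset {nominal}",
            stacklevel=3,
        )
        logger.warning("stitch fallback to nominal offset %s (confidence %.2f)", nominal, conf)
        return nominal, False
    return est, True


def _aligned_correlation(ref: np.ndarray, mov: np.ndarray, offset: tuple[int, int]) -> float:
    dy, dx = offset
    h, w = ref.shape
    ry0, my0 = (dy, 0) if dy >= 0 else (0, -dy)
    rx0, mx0 = (dx, 0) if dx >= 0 else (0, -dx)
    oh = min(h - ry0, h - my0)
    ow = min(w - rx0, w - mx0)
    if oh <= 1 or ow <= 1:
        return 0.0
    a = ref[ry0 : ry0 + oh, rx0 : rx0 + ow].astype(np.float64).ravel()
    b = mov[my0 : my0 + oh, mx0 : mx0 + ow].astype(np.float64).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def stitch_tiles(tileset: TileSet, min_confidence: float = 0.5) -> np.ndarray:
    """Assemble a tile grid into one mosaic.

    Pairwise offsets are estimated against the left neighbour (first
    column: against the top neighbour) and accumulated row-major from the
    top-left anchor.  Overlaps are blended with linear feathering
    (weights ramp from the tile border inwards).
    """
    rows, cols = tileset.grid_shape
    th, tw = tileset.tile_shape
    if rows == 1 and cols == 1:
        return tileset.tiles[0][0].copy()

    true = tileset.true_offsets_px
    pos = [[(0, 0)] * cols for _ in range(rows)]
    for r in range(rows):
        for c in range(cols):
            if r == 0 and c == 0:
                continue
            if c > 0:
                ref, mov = tileset.tiles[r][c - 1], tileset.tiles[r][c]
                nominal = (
                    true[r][c][0] - true[r][c - 1][0],
                    true[r][c][1] - true[r][c - 1][1],
                )
                rel, _ = _pair_offset(ref, mov, nominal, axis=1, min_confidence=min_confidence)
                base = pos[r][c - 1]
            else:
                ref, mov = tileset.tiles[r - 1][c], tileset.tiles[r][c]
                nominal = (
                    true[r][c][0] - true[r - 1][c][0],
                    true[r][c][1] - true[r - 1][c][1],
                )
                rel, _ = _pair_offset(ref, mov, nominal, axis=0, min_confidence=min_confidence)
                base = pos[r - 1][c]
            pos[r][c] = (base[0] + rel[0], base[1] + rel[1])

    min_y = min(p[0] for row in pos for p in row)
    min_x = min(p[1] for row in pos for p in row)
    pos = [[(p[0] - min_y, p[1] - min_x) for p in row] for row in pos]
    out_h = max(p[0] for row in pos for p in row) + th
    out_w = max(p[1] for row in pos for p in row) + tw

    # linear feather: weight = distance to nearest tile border (>= 1)
    wy = np.minimum(np.arange(th) + 1, th - np.arange(th))
    wx = np.minimum(np.arange(tw) + 1, tw - np.arange(tw))
    weight = np.outer(wy, wx).astype(np.float64)

    acc = np.zeros((out_h, out_w), np.float64)
    wacc = np.zeros((out_h, out_w), np.float64)
    for r in range(rows):
        for c in range(cols):
            oy, ox = pos[r][c]
            acc[oy : oy + th, ox : ox + tw] += tileset.tiles[r][c] * weight
            wacc[oy : oy + th, ox : ox + tw] += weight
    out = acc / np.maximum(wacc, 1e-12)
    return np.clip(np.rint(out), 0, MAX_GRAY).astype(np.uint16)


# --------------------------------------------------------------------------
# ROI handling
# --------------------------------------------------------------------------

def load_rois(path: str | Path) -> list[RoiSpec]:
    """Read the ROI TXT dialect: whitespace-separated ``x y width height``,
    ``#`` comments and blank lines ignored, file line number as roi_id."""
    path = Path(path)
    rois: list[RoiSpec] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 4:
            raise ValueError(f"{path}: expected 4 fields (x y w h) at line {lineno}, got {len(tokens)}")
        try:
            x, y, w, h = (int(t) for t in tokens)
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer token at line {lineno}: {raw!r}") from exc
        if w <= 0 or h <= 0:
            raise ValueError(f"{path}: non-positive ROI dimension at line {lineno}")
        rois.append(RoiSpec(roi_id=lineno, x0=x, y0=y, width=w, height=h))
    return rois


# --------------------------------------------------------------------------
# per-ROI processing
# --------------------------------------------------------------------------

def equalize(
    roi_image: np.ndarray, method: Literal["stretch", "hist"] = "stretch"
) -> tuple[np.ndarray, bool]:
    """Contrast-normalise a grayscale crop to the full 16-bit range.

    ``stretch`` (default) linearly maps [min, max] to [0, 65535], which
    preserves relative intensity separations; ``hist`` is classic
    histogram equalization (rank mapping, flattens the histogram).  Both
    preserve pixel rank order.  Returns ``(image, degenerate)`` where
    ``degenerate`` flags a constant input, returned unchanged.
    """
    img = np.asarray(roi_image)
    lo, hi = int(img.min()), int(img.max())
    if hi == lo:
        warnings.warn("equalize: constant ROI left unchanged", stacklevel=2)
        return img.copy(), True
    if method == "stretch":
        out = (img.astype(np.float64) - lo) / (hi - lo) * MAX_GRAY
        return np.rint(out).astype(np.uint16), False
    if method == "hist":
        values, counts = np.unique(img, return_counts=True)
        cdf = np.cumsum(counts) / img.size
        cdf_min = cdf[0]
        mapped = (cdf - cdf_min) / (1.0 - cdf_min) * MAX_GRAY
        lut = dict(zip(values.tolist(), np.rint(mapped).astype(np.uint16).tolist()))
        out = np.vectorize(lut.__getitem__, otypes=[np.uint16])(img)
        return out, False
    raise ValueError(f"unknown equalize method {method!r}")


def binarize(
    roi_image: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    cutoff: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Mask of pixels strictly above the cut-off (gap signal).

    The cut-off is either fixed or computed per ROI by Otsu's
    between-class-variance criterion.  A single-level image yields an
    empty mask and a warning.  Returns ``(mask, cutoff_used)``.
    """
    img = np.asarray(roi_image)
    if img.min() == img.max():
        warnings.warn("binarize: degenerate single-level histogram, empty mask", stacklevel=2)
        return np.zeros(img.shape, bool), None
    if method == "fixed":
        if cutoff is None:
            raise ValueError("fixed-threshold binarization needs a cutoff")
        thr = float(cutoff)
    elif method == "otsu":
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > thr, thr


def label_blobs(mask: np.ndarray, min_area_px: int = 4, connectivity: int = 2) -> list[Blob]:
    """8-connected components of a binary mask, small specks discarded."""
    labels = skmeasure.label(mask, connectivity=connectivity)
    blobs: list[Blob] = []
    for rp in skmeasure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        blobs.append(
            Blob(
                label=rp.label,
                coords=rp.coords,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
                bbox=tuple(rp.bbox),
            )
        )
    return blobs


def select_central_blob(blobs: Sequence[Blob], roi: RoiSpec) -> Blob | None:
    """The blob whose centroid is nearest the ROI centre (the gap).

    The ROI framing is assumed to have centred the gap; competing blobs
    (junction fragments, neighbouring gaps) sit towards the edges.  Ties
    break towards larger area, then lower label index.
    """
    if not blobs:
        return None
    cy = (roi.height - 1) / 2.0
    cx = (roi.width - 1) / 2.0

    def key(b: Blob):
        d = math.hypot(b.centroid[0] - cy, b.centroid[1] - cx)
        return (d, -b.area_px, b.label)

    return min(blobs, key=key)


def _perimeter_edge_count(coords: np.ndarray, shape: tuple[int, int]) -> float:
    """Crack-boundary length: count of pixel edges between blob and
    background (a 5x5 square scores 20)."""
    mask = np.zeros((shape[0] + 2, shape[1] + 2), bool)
    mask[coords[:, 0] + 1, coords[:, 1] + 1] = True
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((mask & ~np.roll(mask, shift, axis=ax)).sum())
    return float(edges)


def _perimeter_contour(coords: np.ndarray, shape: tuple[int, int]) -> float:
    """Sub-pixel boundary length from the marching-squares contour of the
    padded mask, with a 3-point cyclic moving average that removes the
    staircase bias; accurate for smooth blobs (disc of radius 20 ~ 2 pi 20)."""
    mask = np.zeros((shape[0] + 2, shape[1] + 2), np.float64)
    mask[coords[:, 0] + 1, coords[:, 1] + 1] = 1.0
    total = 0.0
    for contour in skmeasure.find_contours(mask, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed and len(contour) > 1 else contour
        if closed and len(pts) >= 3:
            pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
            seg = np.vstack([pts, pts[:1]])
        else:
            seg = pts
        total += float(np.sqrt((np.diff(seg, axis=0) ** 2).sum(axis=1)).sum())
    return total


def measure(
    blob: Blob,
    pixel_size_um: float,
    roi_shape: tuple[int, int] | None = None,
    perimeter_method: Literal["contour", "edge_count"] = "contour",
) -> GapMeasure:
    """Physical geometry of a blob: area, perimeter, shape factor.

    Two perimeter conventions are offered: ``contour`` traces the 0.5-level
    boundary polygon of the mask (sub-pixel, unbiased for smooth shapes)
    and ``edge_count`` counts exposed pixel edges (exact for axis-aligned
    rectangles, overestimates curved boundaries).  The shape factor
    4 pi A / P^2 approaches 1 for circular gaps under ``contour``.
    """
    if blob.area_px == 0:
        raise ValueError("cannot measure an empty blob")
    if roi_shape is None:
        roi_shape = (int(blob.bbox[2]), int(blob.bbox[3]))
    if perimeter_method == "edge_count":
        perim_px = _perimeter_edge_count(blob.coords, roi_shape)
    elif perimeter_method == "contour":
        perim_px = _perimeter_contour(blob.coords, roi_shape)
    else:
        raise ValueError(f"unknown perimeter method {perimeter_method!r}")
    area_um2 = blob.area_px * pixel_size_um**2
    perimeter_um = perim_px * pixel_size_um
    shape_factor = 4.0 * math.pi * area_um2 / perimeter_um**2
    return GapMeasure(
        roi_id=-1,
        area_px=blob.area_px,
        area_um2=area_um2,
        perimeter_um=perimeter_um,
        shape_factor=shape_factor,
        centroid=blob.centroid,
    )


# --------------------------------------------------------------------------
# orchestration and statistics
# --------------------------------------------------------------------------

def analyze(
    image: np.ndarray,
    rois: Sequence[RoiSpec],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Run the per-ROI chain over a stitched image.

    Output rows follow the ROI order; ROIs in which no blob survives the
    minimum-area filter are recorded with ``found=False`` and NaN
    measures.  An ROI entirely outside the image raises.
    """
    h, w = image.shape
    records = []
    for roi in rois:
        x0, y0 = max(0, roi.x0), max(0, roi.y0)
        x1, y1 = min(w, roi.x0 + roi.width), min(h, roi.y0 + roi.height)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"ROI {roi.roi_id} lies fully outside the {w}x{h} image")
        crop = image[y0:y1, x0:x1]
        if config.invert:
            crop = MAX_GRAY - crop.astype(np.int64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-ROI warnings become null rows
            eq, degenerate = equalize(crop, method=config.equalize_method)
            mask, thr = binarize(eq, method=config.threshold_method, cutoff=config.fixed_cutoff)
        blobs = label_blobs(mask, min_area_px=config.min_blob_area_px, connectivity=config.connectivity)
        clipped = RoiSpec(roi.roi_id, x0, y0, x1 - x0, y1 - y0)
        chosen = select_central_blob(blobs, clipped)
        if chosen is None:
            logger.info("ROI %d: no blob found (threshold %s)", roi.roi_id, thr)
            records.append(
                {
                    "roi_id": roi.roi_id, "found": False, "area_px": np.nan, "area_um2": np.nan,
                    "perimeter_um": np.nan, "shape_factor": np.nan,
                    "centroid_x": np.nan, "centroid_y": np.nan,
                }
            )
            continue
        m = measure(
            chosen,
            config.pixel_size_um,
            roi_shape=crop.shape,
            perimeter_method=config.perimeter_method,
        )
        logger.debug("ROI %d: threshold %s, area %d px", roi.roi_id, thr, m.area_px)
        records.append(
            {
                "roi_id": roi.roi_id,
                "found": True,
                "area_px": m.area_px,
                "area_um2": m.area_um2,
                "perimeter_um": m.perimeter_um,
                "shape_factor": m.shape_factor,
                "centroid_x": x0 + chosen.centroid[1],
                "centroid_y": y0 + chosen.centroid[0],
            }
        )
    return pd.DataFrame(records, columns=PER_GAP_COLUMNS)


def summarize(
    table: pd.DataFrame,
    condition: str,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 12,
) -> GapStats:
    """Aggregate a per-gap table: count, total area, area histogram.

    Default binning is log-spaced over the observed area range with
    ``n_bins`` bins; explicit ``bin_edges`` (um^2) override it.
    """
    found = table[table["found"] == True] if len(table) else table  # noqa: E712
    n = int(len(found))
    total = float(found["area_um2"].sum()) if n else 0.0
    if n == 0:
        edges = np.asarray(bin_edges) if bin_edges is not None else np.array([])
        counts = np.zeros(max(len(edges) - 1, 0), int)
        return GapStats(condition, 0, 0.0, edges, counts, table)
    areas = found["area_um2"].to_numpy(float)
    if bin_edges is None:
        lo, hi = float(areas.min()), float(areas.max())
        if lo == hi:  # single distinct area: widen symmetrically
            lo, hi = lo * 0.9, hi * 1.1
        bin_edges = np.geomspace(max(lo, 1e-6), hi, n_bins + 1)
        bin_edges[0] = min(bin_edges[0], lo)  # guarantee inclusion
        bin_edges[-1] = max(bin_edges[-1], hi)
    counts, edges = np.histogram(areas, bins=np.asarray(bin_edges, float))
    return GapStats(condition, n, total, edges, counts, table)


def percent_change(stats: GapStats, control_stats: GapStats) -> float:
    """100 x (A - A_ctrl)/A_ctrl on total gap area vs the control."""
    if control_stats.total_area_um2 <= 0:
        raise ValueError("undefined baseline: control total gap area is zero")
    return 100.0 * (stats.total_area_um2 - control_stats.total_area_um2) / control_stats.total_area_um2


def stats_frame(stats: GapStats) -> pd.DataFrame:
    """Histogram CSV layout: bin_lo, bin_hi, count."""
    if len(stats.bin_edges) < 2:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    return pd.DataFrame(
        {"bin_lo": stats.bin_edges[:-1], "bin_hi": stats.bin_edges[1:], "count": stats.counts}
    )


def save_overlay(
    image: np.ndarray,
    rois: Sequence[RoiSpec],
    table: pd.DataFrame,
    path,
    dpi: int = 120,
) -> None:
    """QC figure: the mosaic with ROI rectangles (green = gap found,
    red = none) and measured gap centroids."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(8, 8 * image.shape[0] / image.shape[1]))
    ax.imshow(image, cmap="gray", interpolation="nearest")
    found = dict(zip(table["roi_id"], table["found"]))
    for roi in rois:
        ok = bool(found.get(roi.roi_id, False))
        ax.add_patch(
            Rectangle((roi.x0, roi.y0), roi.width, roi.height,
                      fill=False, linewidth=0.8, edgecolor="lime" if ok else "red")
        )
    hits = table[table["found"] == True]  # noqa: E712
    ax.plot(hits["centroid_x"], hits["centroid_y"], "+", color="yellow", markersize=4)
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
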