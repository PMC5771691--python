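"""Histology image quantification: Purkinje-cell linear density along the
cell layer, stain-positive area fraction, tiled cell counting, and
phagosome (CD68-type) puncta sizing inside cell masks.

Operators consume single-channel rasters with a physical pixel size plus
either detected/ground-truth object lists or simple thresholded masks.
Pixel coordinates are 0-based (row, col); counting fields are half-open
rectangles so adjacent fields never double count.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import filters as skfilters
from skimage import measure as skmeasure

__all__ = [
    "SyntheticImage",
    "GroundTruth",
    "polyline_length_um",
    "pc_linear_density",
    "signal_area_fraction",
    "tile_cell_density",
    "puncta_size_stats",
    "PunctaStats",
]


@dataclass
class GroundTruth:
    """Known scene content for a synthetic image.

    All coordinates are (row, col) pixels within the image bounds.
    ``layer_path`` is a polyline tracing the cell layer; ``puncta_areas_um2``
    are the as-drawn (rasterized) puncta areas.
    """

    soma_centers: list[tuple[float, float]] = field(default_factory=list)
    soma_radius_px: float = 0.0
    layer_path: list[tuple[float, float]] = field(default_factory=list)
    cell_centers: list[tuple[float, float]] = field(default_factory=list)
    puncta_areas_um2: list[float] = field(default_factory=list)
    coverage_fraction: float | None = None

    def to_json(self, path: str | pathlib.Path) -> pathlib.Path:
        path = pathlib.Path(path)
        payload = {
            "soma_centers": [list(c) for c in self.soma_centers],
            "soma_radius_px": self.soma_radius_px,
            "layer_path": [list(c) for c in self.layer_path],
            "cell_centers": [list(c) for c in self.cell_centers],
            "puncta_areas_um2": list(self.puncta_areas_um2),
            "coverage_fraction": self.coverage_fraction,
        }
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "GroundTruth":
        d = json.loads(pathlib.Path(path).read_text(encoding="utf-8"))
        return cls(
            soma_centers=[tuple(c) for c in d.get("soma_centers", [])],
            soma_radius_px=float(d.get("soma_radius_px", 0.0)),
            layer_path=[tuple(c) for c in d.get("layer_path", [])],
            cell_centers=[tuple(c) for c in d.get("cell_centers", [])],
            puncta_areas_um2=[float(a) for a in d.get("puncta_areas_um2", [])],
            coverage_fraction=d.get("coverage_fraction"),
        )


@dataclass
class SyntheticImage:
    """Single-channel raster with physical pixel size and channel label."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "calbindin"
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a non-empty 2-d array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def save_tiff(self, path: str | pathlib.Path) -> pathlib.Path:
        import tifffile

        path = pathlib.Path(path)
        tifffile.imwrite(
            path,
            self.pixels,
            metadata={"pixel_size_um": self.pixel_size_um, "channel": self.channel},
        )
        return path

    @classmethod
    def load_tiff(
        cls, path: str | pathlib.Path, pixel_size_um: float | None = None, channel: str = ""
    ) -> "SyntheticImage":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            pixels = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if pixel_size_um is None:
            pixel_size_um = float(meta.get("pixel_size_um", 1.0))
        channel = channel or str(meta.get("channel", ""))
        return cls(pixels=pixels, pixel_size_um=pixel_size_um, channel=channel)


# ---------------------------------------------------------------------------
# geometry helpers

def _point_segment_dist(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    seg = p1 - p0
    denom = float(seg @ seg)
    if denom == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ seg / denom, 0.0, 1.0)
    proj = p0 + t[:, None] * seg
    return np.linalg.norm(points - proj, axis=1)


def _dist_to_polyline(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    d = np.full(len(points), np.inf)
    for p0, p1 in zip(path, path[1:]):
        d = np.minimum(d, _point_segment_dist(points, p0, p1))
    return d


def polyline_length_um(path: Sequence[tuple[float, float]], pixel_size_um: float) -> float:
    """Physical length of a pixel-coordinate polyline in micrometres."""
    arr = np.asarray(path, dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("path must contain at least two points")
    return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1))) * pixel_size_um


# ---------------------------------------------------------------------------
# operators

def pc_linear_density(
    soma_centers: Sequence[tuple[float, float]],
    layer_path: Sequence[tuple[float, float]],
    pixel_size_um: float,
    capture_distance_um: float | None = None,
    soma_radius_um: float = 10.0,
    per_um: float = 100.0,
) -> float:
    """Linear soma density along a cell layer, in cells per ``per_um`` µm.

    Somata within ``capture_distance_um`` of the polyline (default 1.5×
    the soma radius) are counted and divided by the physical path length.
    An empty detection set gives 0; a degenerate path is an error.
    """
    length = polyline_length_um(layer_path, pixel_size_um)
    if length <= 0:
        raise ValueError("layer path has zero length")
    if len(soma_centers) == 0:
        return 0.0
    if capture_distance_um is None:
        capture_distance_um = 1.5 * soma_radius_um
    pts = np.asarray(soma_centers, dtype=float)
    d_um = _dist_to_polyline(pts, np.asarray(layer_path, dtype=float)) * pixel_size_um
    count = int(np.sum(d_um <= capture_distance_um))
    return count / length * per_um


def signal_area_fraction(
    image: SyntheticImage | np.ndarray,
    rule: str = "background_k_sd",
    k: float = 3.0,
    threshold: float | None = None,
    background_mask: np.ndarray | None = None,
) -> float:
    """Percent of image area at or above a positive-signal threshold.

    Threshold rules:

    * ``background_k_sd`` (default): mean + k·SD of a background sample;
      the background is ``background_mask`` if given, otherwise the pixels
      below the Otsu split (an automated stand-in for thresholding against
      the dark background).  Pixels strictly above the threshold count as
      positive, so a flat image has zero signal.  An empty background
      sample is an error.
    * ``otsu``: Otsu's method.
    * ``fixed``: explicit ``threshold``; pixels at or above it count.
    """
    pixels = image.pixels if isinstance(image, SyntheticImage) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("image is empty")
    flat = pixels.astype(float)
    if rule == "fixed":
        if threshold is None:
            raise ValueError("fixed rule requires an explicit threshold")
        return float(np.mean(flat >= float(threshold))) * 100.0
    if rule == "otsu":
        if np.ptp(flat) == 0:
            return 0.0
        thr = float(skfilters.threshold_otsu(flat))
        return float(np.mean(flat > thr)) * 100.0
    if rule == "background_k_sd":
        if background_mask is not None:
            bg = flat[np.asarray(background_mask, dtype=bool)]
            if bg.size == 0:
                raise ValueError("background region is empty")
        else:
            if np.ptp(flat) == 0:
                return 0.0
            bg = flat[flat <= skfilters.threshold_otsu(flat)]
        thr = float(bg.mean() + k * bg.std())
        return float(np.mean(flat > thr)) * 100.0
    raise ValueError(f"unknown threshold rule {rule!r}")


@dataclass(frozen=True)
class FieldCount:
    origin_px: tuple[float, float]
    side_um: float
    count: int


def tile_cell_density(
    cell_centers: Sequence[tuple[float, float]],
    field_origins_px: Sequence[tuple[float, float]],
    field_side_um: float,
    pixel_size_um: float,
    image_shape: tuple[int, int] | None = None,
) -> tuple[int, list[FieldCount]]:
    """Count cells per square field and the summed total across fields.

    A cell belongs to a field when its centroid lies inside the half-open
    square [r0, r0+side) × [c0, c0+side) in pixels.  Fields must fit inside
    ``image_shape`` when it is given.
    """
    side_px = field_side_um / pixel_size_um
    if image_shape is not None:
        h, w = image_shape
        if side_px > h or side_px > w:
            raise ValueError("field larger than image")
        for r0, c0 in field_origins_px:
            if r0 < 0 or c0 < 0 or r0 + side_px > h or c0 + side_px > w:
                raise ValueError(f"field at {(r0, c0)} does not fit inside the image")
    pts = np.asarray(cell_centers, dtype=float).reshape(-1, 2)
    fields = []
    total = 0
    for r0, c0 in field_origins_px:
        if len(pts):
            inside = (
                (pts[:, 0] >= r0)
                & (pts[:, 0] < r0 + side_px)
                & (pts[:, 1] >= c0)
                & (pts[:, 1] < c0 + side_px)
            )
            cnt = int(np.sum(inside))
        else:
            cnt = 0
        total += cnt
        fields.append(FieldCount((float(r0), float(c0)), field_side_um, cnt))
    return total, fields


@dataclass(frozen=True)
class PunctaStats:
    areas_um2: tuple[float, ...]
    mean_area_um2: float
    per_cell_mean_um2: dict[int, float]
    n_puncta: int
    warning: str = ""


def puncta_size_stats(
    puncta_image: SyntheticImage | np.ndarray,
    cell_masks: np.ndarray,
    pixel_size_um: float | None = None,
    threshold: float | None = None,
    rule: str = "otsu",
    min_size_px: int = 2,
    connectivity: int = 2,
) -> PunctaStats:
    """Mean area (µm²) of thresholded puncta inside mask-positive cells.

    ``cell_masks`` is a boolean mask or an integer label image sharing the
    puncta channel's geometry.  Puncta are connected components
    (8-connected by default) of the thresholded channel that overlap a
    cell; components smaller than ``min_size_px`` pixels are dropped.  With
    no mask-positive cells an empty result carrying a warning is returned
    (regions with too few labeled cells are reported, not guessed at).
    """
    if isinstance(puncta_image, SyntheticImage):
        pixels = puncta_image.pixels.astype(float)
        if pixel_size_um is None:
            pixel_size_um = puncta_image.pixel_size_um
    else:
        pixels = np.asarray(puncta_image, dtype=float)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for a bare array")
    cell_masks = np.asarray(cell_masks)
    if cell_masks.shape != pixels.shape:
        raise ValueError("cell masks and puncta channel must share geometry")
    labels = (
        cell_masks.astype(int)
        if cell_masks.dtype != bool
        else skmeasure.label(cell_masks, connectivity=2)
    )
    if labels.max() == 0:
        return PunctaStats((), float("nan"), {}, 0, warning="no mask-positive cells")

    if threshold is not None:
        binary = pixels >= float(threshold)
    elif rule == "otsu" and np.ptp(pixels) > 0:
        binary = pixels > skfilters.threshold_otsu(pixels)
    else:
        binary = pixels > 0
    comp = skmeasure.label(binary, connectivity=connectivity)

    areas: list[float] = []
    per_cell: dict[int, list[float]] = {}
    for region in skmeasure.regionprops(comp):
        if region.area < min_size_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        overlapped = labels[rr, cc]
        hit = np.unique(overlapped[overlapped > 0])
        if hit.size == 0:
            continue
        area_um2 = float(region.area) * pixel_size_um**2
        areas.append(area_um2)
        # assign the punctum to the cell covering most of it
        counts = {int(c): int(np.sum(overlapped == c)) for c in hit}
        owner = max(counts, key=counts.get)
        per_cell.setdefault(owner, []).append(area_um2)

    if not areas:
        return PunctaStats((), float("nan"), {}, 0, warning="no puncta inside cells")
    return PunctaStats(
        areas_um2=tuple(areas),
        mean_area_um2=float(np.mean(areas)),
        per_cell_mean_um2={c: float(np.mean(v)) for c, v in per_cell.items()},
        n_puncta=len(areas),
    )
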