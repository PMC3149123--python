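"""Threshold, label and measure mitochondrial clusters in section images.

Mirrors the classic ImageJ "threshold → Analyse Particles" workflow: a global
threshold (fixed or Otsu) separates stained mitochondria from background,
8-connected components are measured, and particles smaller than a single
mitochondrion (0.2 µm², from the 0.5–1 µm organelle diameter) are discarded
as noise.  Peri-nuclear ring formation is scored as the ratio of mean annulus
intensity to mean cytoplasm intensity, and the aggregation pattern is
classified from the cluster-count/mean-area summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

__all__ = [
    "MitoImage",
    "ClusterSet",
    "RingResult",
    "threshold_image",
    "label_clusters",
    "ring_score",
    "classify_pattern",
]


@dataclass
class MitoImage:
    """A single-channel intensity raster with physical pixel size.

    Origin is the top-left corner; x runs rightward and y downward.  Areas
    derived from the raster are always reported in µm² via
    ``pixel_size_um**2``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if np.any(np.asarray(px, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def threshold_image(img: MitoImage, method: str = "otsu", value: float | None = None) -> np.ndarray:
    """Binarize an image with a fixed or Otsu threshold.

    Parameters
    ----------
    img
        Input image; 8- or 16-bit rasters are handled in floating point.
    method
        ``"otsu"`` — threshold maximizing between-class variance on a
        256-bin histogram of the intensity range; ``"fixed"`` — use ``value``.
    value
        Threshold for ``method="fixed"``.

    Returns
    -------
    mask : ndarray of bool
        True where intensity is strictly above the threshold.
    """
    data = np.asarray(img.pixels, dtype=float)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    elif method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError("cannot Otsu-threshold a constant image: no separable classes")
        thr = float(filters.threshold_otsu(data, nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return data > thr


@dataclass
class ClusterSet:
    """Labeled mitochondrial clusters and their summary statistics.

    ``labels`` is an integer raster (0 = background) covering exactly the
    retained foreground; ``clusters`` holds per-cluster measurements with
    ``area_um2 = pixel_count * pixel_size_um**2``; ``filtered_pixels`` counts
    foreground pixels dropped by the minimum-area filter.
    """

    labels: np.ndarray
    clusters: list[dict]
    pixel_size_um: float
    filtered_pixels: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([c["area_um2"] for c in self.clusters], dtype=float)

    @property
    def summary(self) -> dict:
        areas = self.areas_um2
        n = areas.size
        mean = float(areas.mean()) if n else math.nan
        sem = float(areas.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        return {"n_clusters": n, "mean_area_um2": mean, "sem_area_um2": sem}


def label_clusters(
    mask: np.ndarray,
    pixel_size_um: float,
    connectivity: int = 8,
    min_area_um2: float = 0.2,
) -> ClusterSet:
    """Label connected foreground components and measure their areas.

    Components are found under 8-connectivity by default (the ImageJ Analyse
    Particles convention; pass ``connectivity=4`` for edge-only adjacency)
    and components with area below ``min_area_um2`` — smaller than one
    mitochondrion — are discarded.  An empty mask yields an empty ClusterSet.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(mask, dtype=bool)
    skimage_conn = 2 if connectivity == 8 else 1
    raw = measure.label(mask, connectivity=skimage_conn)

    out = np.zeros_like(raw, dtype=np.int32)
    clusters: list[dict] = []
    filtered_pixels = 0
    px_area = pixel_size_um**2
    for region in measure.regionprops(raw):
        area = region.area * px_area
        if area < min_area_um2:
            filtered_pixels += int(region.area)
            continue
        new_id = len(clusters) + 1
        out[raw == region.label] = new_id
        clusters.append(
            {
                "id": new_id,
                "pixel_count": int(region.area),
                "area_um2": float(area),
                "centroid": tuple(map(float, region.centroid)),
            }
        )
    return ClusterSet(
        labels=out,
        clusters=clusters,
        pixel_size_um=pixel_size_um,
        filtered_pixels=filtered_pixels,
    )


@dataclass(frozen=True)
class RingResult:
    """Peri-nuclear ring score: annulus-to-cytoplasm mean-intensity ratio."""

    score: float
    present: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("ring score must be non-negative")


def ring_score(
    img: MitoImage,
    center: tuple[float, float],
    r_um: float,
    width_um: float,
    cell_mask: np.ndarray,
    theta_ring: float = 1.5,
) -> RingResult:
    """Score a candidate peri-nuclear mitochondrial ring.

    The score is the mean intensity inside the annulus ``[r, r + width]``
    around ``center`` divided by the mean intensity of the remaining
    cytoplasm (cell mask minus the annulus and the enclosed nucleus disc).
    A ring is called present when the score reaches ``theta_ring``.

    ``center`` is (row, col) in pixels; radii are in µm.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != img.shape:
        raise ValueError("cell_mask shape must match the image")
    cy, cx = center
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    dist_um = np.hypot(yy - cy, xx - cx) * img.pixel_size_um
    annulus = (dist_um >= r_um) & (dist_um <= r_um + width_um)
    if np.any(annulus & ~cell_mask):
        raise ValueError("annulus extends outside the cell mask")
    cytoplasm = cell_mask & (dist_um > r_um + width_um)
    if not np.any(annulus):
        raise ValueError("annulus contains no pixels")
    if not np.any(cytoplasm):
        raise ValueError("cytoplasm region contains no pixels")
    data = np.asarray(img.pixels, dtype=float)
    score = float(data[annulus].mean() / data[cytoplasm].mean())
    return RingResult(score=score, present=score >= theta_ring)


def classify_pattern(
    summary: dict,
    area_threshold_um2: float = 3.5,
    count_threshold: float = 85.0,
) -> str:
    """Classify a cluster summary as aggregated, dispersed or intermediate.

    Few large clusters (mean area above ~3.5 µm², fewer than ~85 per section)
    is the aggregated regime; many small clusters is dispersed; anything else
    — including the exact boundary — is intermediate.  Thresholds sit between
    the two regimes' typical values (4.7 µm²/66 per section vs 2.6 µm²/102)
    and are configurable.
    """
    mean_area = summary["mean_area_um2"]
    n = summary["n_clusters"]
    if mean_area > area_threshold_um2 and n < count_threshold:
        return "aggregated"
    if mean_area < area_threshold_um2 and n > count_threshold:
        return "dispersed"
    return "intermediate"
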