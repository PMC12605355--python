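"""Image-level distribution indicators.

Combines the per-gland morphology with whole-image measures: gland count,
total gland area, density (gland area / tarsal area), loss ratio
(1 - density when glands lie inside the tarsus), nearest distances between
left-to-right adjacent glands, and disorder (population standard deviation
of those distances).  The result is one ``ImageIndicators`` row per image —
the nine-indicator feature vector fed to the grading statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateTarsusError, DimensionError
from .geometry import measure_gland
from .mask_io import ContourSet, SegmentationMask, extract_contours, open_mask, LABEL_STRUCTURE

#: Indicator column names in canonical order (the feature row for statistics).
INDICATOR_COLUMNS = (
    "gland_count",
    "total_gland_area",
    "density",
    "loss_ratio",
    "mean_width",
    "mean_length",
    "mean_distortion",
    "mean_adjacent_distance",
    "disorder",
)


@dataclass(frozen=True)
class ImageIndicators:
    """Per-image indicator record; undefined values are NaN."""

    image_id: str
    gland_count: int
    total_gland_area: int
    tarsus_area: int
    density: float
    loss_ratio: float
    mean_width: float
    mean_length: float
    mean_distortion: float
    mean_adjacent_distance: float
    disorder: float

    def as_dict(self) -> dict:
        return asdict(self)


def gland_count(contours: ContourSet) -> int:
    """Number of surviving (filtered) gland contours."""
    return len(contours)


def total_gland_area(contours: ContourSet) -> int:
    """Sum of the filled outer-boundary areas of all glands (px^2)."""
    return int(sum(c.area_px for c in contours))


def gland_density(total_area: float, tarsus_area: float) -> float:
    """Total gland area divided by tarsal area."""
    if tarsus_area <= 0:
        raise DegenerateTarsusError("tarsus area must be positive")
    return total_area / tarsus_area


def loss_ratio(total_area: float, tarsus_area: float) -> float:
    """(tarsal area - gland area) / tarsal area, clamped to [0, 1]."""
    if tarsus_area <= 0:
        raise DegenerateTarsusError("tarsus area must be positive")
    ratio = (tarsus_area - total_area) / tarsus_area
    if ratio < 0.0:
        warnings.warn("gland area exceeds tarsal area; loss ratio clamped to 0")
        return 0.0
    return min(ratio, 1.0)


def adjacent_nearest_distances(contours: ContourSet) -> list[float]:
    """Nearest boundary-to-boundary distance for each adjacent gland pair.

    Adjacency means consecutive in left-to-right centroid order; the
    distance is the minimum Euclidean distance over all boundary vertex
    pairs of the two glands.  With <= 1 gland the list is empty.
    """
    out: list[float] = []
    for left, right in zip(contours, list(contours)[1:]):
        tree = cKDTree(right.vertices)
        d, _ = tree.query(left.vertices, k=1)
        out.append(float(d.min()))
    return out


def disorder(distances: list[float]) -> float:
    """Population standard deviation of the adjacent-gland distances.

    Empty list -> NaN (undefined); a single distance -> 0.
    """
    if not distances:
        return float("nan")
    return float(np.std(distances))


def tarsus_region_area(tarsus_mask: SegmentationMask) -> int:
    """Filled area of the largest connected tarsus component (px^2).

    Smaller components are ignored with a warning; an empty mask raises.
    """
    labels, n = ndimage.label(tarsus_mask.grid, structure=LABEL_STRUCTURE)
    if n == 0:
        raise DegenerateTarsusError("tarsus mask has no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    if n > 1:
        warnings.warn(f"tarsus mask has {n} components; using the largest only")
    largest = labels == (int(np.argmax(sizes)) + 1)
    return int(ndimage.binary_fill_holes(largest).sum())


def _nanmean(values: list[float]) -> float:
    finite = [v for v in values if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def compute_indicators(
    gland_mask: SegmentationMask,
    tarsus_mask: SegmentationMask,
    image_id: str,
    min_area: int = 10,
    min_points: int = 4,
    n_stations: int = 50,
) -> ImageIndicators:
    """Run the full indicator pipeline on one gland/tarsus mask pair.

    The gland mask is opened (3x3 cross), decomposed into filtered sorted
    contours, and each gland measured; per-image morphology means exclude
    degenerate (NaN) glands.  The tarsal area is the filled area of the
    largest tarsus-mask component.
    """
    if gland_mask.grid.shape != tarsus_mask.grid.shape:
        raise DimensionError(
            f"gland/tarsus shapes differ: {gland_mask.grid.shape} vs {tarsus_mask.grid.shape}"
        )
    tarsus_area = tarsus_region_area(tarsus_mask)
    contours = extract_contours(open_mask(gland_mask), min_area, min_points)
    count = gland_count(contours)
    total_area = total_gland_area(contours)
    morphs = [measure_gland(c, n_stations) for c in contours]
    gaps = adjacent_nearest_distances(contours)
    return ImageIndicators(
        image_id=image_id,
        gland_count=count,
        total_gland_area=total_area,
        tarsus_area=tarsus_area,
        density=gland_density(total_area, tarsus_area),
        loss_ratio=loss_ratio(total_area, tarsus_area),
        mean_width=_nanmean([m.width_px for m in morphs]),
        mean_length=_nanmean([m.length_px for m in morphs]),
        mean_distortion=_nanmean([m.distortion for m in morphs]),
        mean_adjacent_distance=_nanmean(gaps),
        disorder=disorder(gaps),
    )
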