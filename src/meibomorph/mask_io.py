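"""Binary segmentation-mask I/O, preprocessing, and contour decomposition.

The unit of analysis is a strictly binary 2D raster (``SegmentationMask``).
Masks are cleaned with one pass of morphological opening (3x3 cross-shaped
element, the standard 3x3 "elliptical" kernel of mainstream vision toolkits),
decomposed into 8-connected components, and each component's outer boundary
becomes a ``GlandContour``.  Components smaller than ``min_area`` filled
pixels or with fewer than ``min_points`` boundary vertices are discarded.
Contours are reported left-to-right by centroid abscissa so downstream
adjacency analysis is deterministic.

Coordinate convention: ``x`` is the column index, ``y`` the row index, origin
at the top-left, pixel centers at integer coordinates.  Contour vertices are
sub-pixel marching-squares points at iso-level 0.5, so they trace the
half-pixel band around the foreground pixel centers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DimensionError, InputError

#: 3x3 cross-shaped structuring element (center + 4-neighbours).
OPENING_STRUCTURE = ndimage.generate_binary_structure(2, 1)

#: 8-connectivity for component labelling.
LABEL_STRUCTURE = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_AREA = 10
DEFAULT_MIN_POINTS = 4


@dataclass(frozen=True, eq=False)
class SegmentationMask:
    """A strictly binary 2D raster.

    Parameters
    ----------
    grid
        Boolean array of shape ``(height, width)``; ``True`` is foreground.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
            raise DimensionError(f"mask must be a non-empty 2D raster, got shape {g.shape}")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True, eq=False)
class GlandContour:
    """One gland: ordered outer-boundary polygon plus filled-region stats.

    ``vertices`` is an ``(n, 2)`` float array of ``(x, y)`` boundary points,
    ``area_px`` the filled (hole-free) pixel count of the component, and
    ``centroid`` the arithmetic mean of the filled-region pixel coordinates.
    """

    vertices: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    filled: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True, eq=False)
class ContourSet:
    """Filtered gland contours in left-to-right centroid order."""

    contours: tuple[GlandContour, ...]
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def __getitem__(self, i):
        return self.contours[i]


@dataclass(frozen=True)
class MaskComparison:
    """Pixelwise confusion counts and the derived overlap ratios.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``iou = TP/(TP+FP+FN)`` and ``f1 = 2TP/(2TP+FP+FN)``.  A 0/0 ratio is
    reported as NaN, never as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    iou: float
    f1: float


def load_mask(path: str | os.PathLike, threshold: int = 0) -> SegmentationMask:
    """Read a PNG/TIFF raster and binarize it.

    Multi-channel images are reduced to one channel by taking the per-pixel
    channel maximum; a pixel is foreground iff its intensity exceeds
    ``threshold`` (default 0, matching 0/255 annotation masks).
    """
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read mask image {path!r}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        img = img.max(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise DimensionError(f"mask image {path!r} is not a non-empty 2D raster")
    return SegmentationMask(img > threshold)


def save_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit 0/255 PNG/TIFF."""
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))


def resize_mask(mask: SegmentationMask, target_h: int, target_w: int) -> SegmentationMask:
    """Nearest-neighbour resize preserving strict binarity.

    Each target pixel copies the source pixel whose center is nearest
    (``src = floor((i + 0.5) * src_size / target_size)``); no interpolation
    touches the binary values.
    """
    if target_h < 1 or target_w < 1:
        raise DimensionError(f"target size must be positive, got {target_h}x{target_w}")
    h, w = mask.grid.shape
    rows = np.minimum(((np.arange(target_h) + 0.5) * h / target_h).astype(int), h - 1)
    cols = np.minimum(((np.arange(target_w) + 0.5) * w / target_w).astype(int), w - 1)
    return SegmentationMask(mask.grid[np.ix_(rows, cols)])


def open_mask(mask: SegmentationMask) -> SegmentationMask:
    """One pass of morphological opening with the 3x3 cross element.

    Erosion followed by dilation; removes specks smaller than the element
    and shaves single-pixel protrusions (e.g. the corners of a square).
    Pixels outside the image count as background.
    """
    opened = ndimage.binary_opening(mask.grid, structure=OPENING_STRUCTURE)
    return SegmentationMask(opened)


def _component_contour(component: np.ndarray) -> np.ndarray | None:
    """Outer boundary polygon of one component as an (n, 2) (x, y) array."""
    padded = np.pad(component, 1).astype(float)
    rings = measure.find_contours(padded, 0.5, fully_connected="high")
    if not rings:
        return None
    outer = max(rings, key=len)  # outer ring has the most vertices
    if len(outer) > 1 and np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]  # drop duplicated closing vertex
    # (row, col) in padded frame -> (x, y) in image frame
    return np.column_stack([outer[:, 1] - 1.0, outer[:, 0] - 1.0])


def extract_contours(
    mask: SegmentationMask,
    min_area: int = DEFAULT_MIN_AREA,
    min_points: int = DEFAULT_MIN_POINTS,
) -> ContourSet:
    """Decompose a mask into filtered, left-to-right sorted gland contours.

    Components are 8-connected; each contributes its outer boundary only,
    with interior holes filled before computing ``area_px`` and the centroid.
    Components with filled area < ``min_area`` or fewer than ``min_points``
    boundary vertices are dropped.
    """
    labels, n = ndimage.label(mask.grid, structure=LABEL_STRUCTURE)
    contours: list[GlandContour] = []
    for idx in range(1, n + 1):
        component = labels == idx
        filled = ndimage.binary_fill_holes(component)
        area = int(filled.sum())
        if area < min_area:
            continue
        verts = _component_contour(component)
        if verts is None or len(verts) < min_points:
            continue
        ys, xs = np.nonzero(filled)
        centroid = (float(xs.mean()), float(ys.mean()))
        contours.append(GlandContour(verts, area, centroid, filled))
    return ContourSet(tuple(sort_contours(contours)), mask.grid.shape)


def sort_contours(contours: list[GlandContour]) -> list[GlandContour]:
    """Stable sort by ascending centroid x, ties broken by ascending y."""
    return sorted(contours, key=lambda c: (c.centroid[0], c.centroid[1]))


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def compare_masks(predicted: SegmentationMask, reference: SegmentationMask) -> MaskComparison:
    """Pixelwise confusion counts and Precision/Recall/IoU/F1 of two masks."""
    if predicted.grid.shape != reference.grid.shape:
        raise DimensionError(
            f"mask shapes differ: {predicted.grid.shape} vs {reference.grid.shape}"
        )
    p, r = predicted.grid, reference.grid
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return MaskComparison(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        iou=_ratio(tp, tp + fp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )
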