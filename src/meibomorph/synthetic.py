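"""Seeded generator of gland/tarsus mask pairs with exact ground truth.

Emulates the 1,280 x 640 eyelid rasters that indicator extraction consumes:
a filled elliptical tarsus band containing 5-30 near-vertical elongated
glands (straight ribbons, circular arcs, or sinusoids) rasterized as the set
of pixels within half a width of an analytic centerline.  Every image comes
with a ``TruthRecord`` holding the per-gland centerline length, width and
curvature and the image-level count, density, loss ratio and adjacent-gap
list, so measurement accuracy can be scored without clinical data.

``generate_graded_dataset`` stratifies the generator by an MGD-like severity
grade 0-3: higher grade means fewer, shorter, thinner, more curved glands
and wider, more variable gaps (see ``GRADE_PARAM_MAP``), mirroring the
directions in which gland dropout and tortuosity evolve with disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GenerationError
from .mask_io import SegmentationMask

#: Arc-length step (px) for densifying analytic centerlines.
CENTERLINE_STEP = 0.25

#: Grade -> generator parameter map: linear trends in grade with seeded
#: jitter.  Directions: higher grade = fewer/shorter/thinner glands, more
#: curvature, more variable spacing (loss ratio and distortion up, density
#: down, disorder up).
GRADE_PARAM_MAP = {
    "n_glands_mean": lambda g: 16.0 - 3.0 * g,
    "n_glands_jitter": 1,
    "width_mean": lambda g: 16.0 - 2.5 * g,
    "width_jitter": 2.0,
    "width_min": 6.0,
    "length_mean": lambda g: 280.0 - 55.0 * g,
    "length_jitter": 30.0,
    "length_min": 80.0,
    "curvature_mean": lambda g: 0.001 + 0.005 * g,
    "curvature_jitter_frac": 0.4,
    "x_jitter_frac": lambda g: 0.04 + 0.05 * g,
}


@dataclass(frozen=True)
class GlandSpec:
    """Analytic description of one gland.

    ``anchor`` is the centerline midpoint (x, y); ``orientation`` the
    centerline tangent at the anchor (radians, CCW from +x); ``curvature``
    the arc curvature (1/px; 0 = straight) or, for sinusoids, the peak
    centerline curvature.
    """

    anchor: tuple[float, float]
    orientation: float
    centerline_length: float
    width: float
    curvature: float = 0.0
    shape: str = "straight"

    def __post_init__(self) -> None:
        if self.width < 3.0:
            raise GenerationError(f"gland width {self.width} < 3 px")
        if self.centerline_length < 20.0:
            raise GenerationError(f"centerline length {self.centerline_length} < 20 px")
        if self.curvature < 0.0:
            raise GenerationError("curvature must be >= 0")
        if self.shape == "arc" and self.curvature * self.centerline_length >= np.pi:
            raise GenerationError("arc would self-overlap (curvature * length >= pi)")
        if self.shape not in ("straight", "arc", "sinusoid"):
            raise GenerationError(f"unknown gland shape {self.shape!r}")


@dataclass(frozen=True)
class TarsusSpec:
    """Filled ellipse: center (x, y) and semi-axes (rx, ry) in px."""

    center: tuple[float, float]
    rx: float
    ry: float


@dataclass(frozen=True)
class ImageSpec:
    """One synthetic image: canvas, tarsus band, gland list, spacing floor."""

    glands: tuple[GlandSpec, ...]
    tarsus: TarsusSpec
    height: int = 640
    width: int = 1280
    min_gap: float = 8.0


@dataclass(frozen=True)
class TruthRecord:
    """Exact ground truth for one generated image."""

    lengths: tuple[float, ...]
    widths: tuple[float, ...]
    curvatures: tuple[float, ...]
    gland_areas: tuple[int, ...]
    count: int
    gland_area_px: int
    tarsus_area_px: int
    density: float
    loss_ratio: float
    gaps: tuple[float, ...]
    gap_std: float
    grade: int | None = None


@dataclass(frozen=True)
class GradedSample:
    """One dataset entry: mask pair plus its truth."""

    image_id: str
    gland_mask: SegmentationMask
    tarsus_mask: SegmentationMask
    truth: TruthRecord


def centerline_points(spec: GlandSpec, step: float = CENTERLINE_STEP) -> np.ndarray:
    """Densify the analytic centerline into an (n, 2) (x, y) polyline."""
    L = spec.centerline_length
    n = max(int(np.ceil(L / step)) + 1, 2)
    s = np.linspace(-L / 2.0, L / 2.0, n)
    u = np.array([np.cos(spec.orientation), np.sin(spec.orientation)])
    nrm = np.array([-u[1], u[0]])
    a = np.asarray(spec.anchor, dtype=float)
    if spec.shape == "straight" or spec.curvature == 0.0:
        return a + s[:, None] * u
    if spec.shape == "arc":
        R = 1.0 / spec.curvature
        alpha = s * spec.curvature
        center = a + R * nrm
        return center + R * (np.sin(alpha)[:, None] * u - np.cos(alpha)[:, None] * nrm)
    # sinusoid: 1.5 lateral cycles; amplitude chosen so the peak centerline
    # curvature A*(2*pi*f/L)^2 equals the requested curvature
    cycles = 1.5
    omega = 2.0 * np.pi * cycles / L
    amp = spec.curvature / omega**2
    lateral = amp * np.sin(omega * (s + L / 2.0))
    return a + s[:, None] * u + lateral[:, None] * nrm


def rasterize_gland(spec: GlandSpec, canvas: tuple[int, int]) -> SegmentationMask:
    """Rasterize one gland: pixels within width/2 of the centerline.

    Deterministic for a fixed spec; raises ``GenerationError`` if the tube
    extends beyond the canvas.
    """
    h, w = canvas
    pts = centerline_points(spec)
    r = spec.width / 2.0
    x0, y0 = np.floor(pts.min(axis=0) - r).astype(int)
    x1, y1 = np.ceil(pts.max(axis=0) + r).astype(int)
    if x0 < 0 or y0 < 0 or x1 >= w or y1 >= h:
        raise GenerationError(
            f"gland extends outside the {h}x{w} canvas (bbox x[{x0},{x1}] y[{y0},{y1}])"
        )
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    dist, _ = cKDTree(pts).query(coords, k=1)
    inside = (dist <= r).reshape(xs.shape)
    grid = np.zeros((h, w), dtype=bool)
    grid[y0 : y1 + 1, x0 : x1 + 1] = inside
    return SegmentationMask(grid)


def rasterize_tarsus(tarsus: TarsusSpec, canvas: tuple[int, int]) -> SegmentationMask:
    """Filled-ellipse tarsus band."""
    h, w = canvas
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = tarsus.center
    grid = ((xs - cx) / tarsus.rx) ** 2 + ((ys - cy) / tarsus.ry) ** 2 <= 1.0
    return SegmentationMask(grid)


def _pair_gap(pts_a: np.ndarray, pts_b: np.ndarray, w_a: float, w_b: float) -> float:
    """Analytic surface-to-surface gap between two gland tubes."""
    d, _ = cKDTree(pts_b).query(pts_a, k=1)
    return float(d.min()) - (w_a + w_b) / 2.0


def generate_image(spec: ImageSpec, grade: int | None = None) -> tuple[SegmentationMask, SegmentationMask, TruthRecord]:
    """Rasterize an ``ImageSpec`` into a gland/tarsus mask pair plus truth.

    Verifies the constructive constraints: every gland inside the tarsus and
    pairwise (left-to-right adjacent) gaps >= ``min_gap``.
    """
    canvas = (spec.height, spec.width)
    tarsus_mask = rasterize_tarsus(spec.tarsus, canvas)
    glands = sorted(spec.glands, key=lambda g: g.anchor[0])
    gland_grid = np.zeros(canvas, dtype=bool)
    areas: list[int] = []
    all_pts: list[np.ndarray] = []
    for g in glands:
        m = rasterize_gland(g, canvas)
        if np.any(m.grid & ~tarsus_mask.grid):
            raise GenerationError("gland extends outside the tarsus region")
        areas.append(m.foreground_count)
        gland_grid |= m.grid
        all_pts.append(centerline_points(g))
    gaps = [
        _pair_gap(all_pts[i], all_pts[i + 1], glands[i].width, glands[i + 1].width)
        for i in range(len(glands) - 1)
    ]
    if any(gap < spec.min_gap for gap in gaps):
        raise GenerationError(f"adjacent gland gap below min_gap={spec.min_gap}")
    gland_area = int(gland_grid.sum())
    tarsus_area = tarsus_mask.foreground_count
    density = gland_area / tarsus_area
    truth = TruthRecord(
        lengths=tuple(g.centerline_length for g in glands),
        widths=tuple(g.width for g in glands),
        curvatures=tuple(g.curvature for g in glands),
        gland_areas=tuple(areas),
        count=len(glands),
        gland_area_px=gland_area,
        tarsus_area_px=tarsus_area,
        density=density,
        loss_ratio=1.0 - density,
        gaps=tuple(gaps),
        gap_std=float(np.std(gaps)) if gaps else float("nan"),
        grade=grade,
    )
    return SegmentationMask(gland_grid), tarsus_mask, truth


def _grade_value(key: str, grade: int):
    v = GRADE_PARAM_MAP[key]
    return v(grade) if callable(v) else v


def random_image_spec(
    grade: int,
    rng: np.random.Generator,
    height: int = 640,
    width: int = 1280,
    min_gap: float = 8.0,
    max_attempts: int = 200,
) -> ImageSpec:
    """Draw one grade-conditioned ``ImageSpec`` by rejection sampling.

    Glands are near-vertical ribbons placed on jittered left-to-right slots
    inside an elliptical tarsus; lengths are capped by the vertical room at
    each slot so placement is always feasible.  Placement retries up to
    ``max_attempts`` times per image before raising ``GenerationError``.
    """
    if grade not in (0, 1, 2, 3):
        raise GenerationError(f"grade must be 0-3, got {grade}")
    tarsus = TarsusSpec(center=(width / 2.0, height / 2.0), rx=0.46 * width, ry=0.42 * height)
    n = int(round(_grade_value("n_glands_mean", grade) + rng.integers(-1, 2)))
    n = max(n, 5)
    # keep the left-to-right slot pitch wide enough for the thinnest gland
    # plus the gap floor, so placement stays feasible on small canvases
    usable = 2 * tarsus.rx * 0.82
    min_pitch = GRADE_PARAM_MAP["width_min"] + min_gap + 8.0
    n = min(n, max(int(usable // min_pitch), 1))
    x_jitter = _grade_value("x_jitter_frac", grade)
    for _ in range(max_attempts):
        glands = _try_place(grade, n, tarsus, rng, x_jitter, min_gap)
        if glands is None:
            continue
        spec = ImageSpec(glands=tuple(glands), tarsus=tarsus, height=height, width=width, min_gap=min_gap)
        try:
            generate_image(spec)  # validates containment and gaps
        except GenerationError:
            continue
        return spec
    raise GenerationError(f"could not place {n} glands after {max_attempts} attempts (grade {grade})")


def _try_place(
    grade: int,
    n: int,
    tarsus: TarsusSpec,
    rng: np.random.Generator,
    x_jitter_frac: float,
    min_gap: float,
) -> list[GlandSpec] | None:
    cx, cy = tarsus.center
    usable = 2 * tarsus.rx * 0.82
    slots = cx - usable / 2 + usable * (np.arange(n) + 0.5) / n
    slot_pitch = usable / n
    width_min = GRADE_PARAM_MAP["width_min"]
    # lateral budget per slot: width + arc sagitta + jitter must leave the
    # gap floor between neighbours
    jitter_px = min(x_jitter_frac * slot_pitch, 0.25 * slot_pitch)
    lat_cap = slot_pitch - min_gap - 2.0 * jitter_px - 1.0
    if lat_cap < width_min:
        jitter_px = max((slot_pitch - min_gap - width_min - 1.0) / 2.0, 0.0)
        lat_cap = slot_pitch - min_gap - 2.0 * jitter_px - 1.0
        if lat_cap < width_min:
            return None
    glands: list[GlandSpec] = []
    for sx in slots:
        x = sx + rng.uniform(-1.0, 1.0) * jitter_px
        w_g = np.clip(
            _grade_value("width_mean", grade) + rng.uniform(-1, 1) * GRADE_PARAM_MAP["width_jitter"],
            width_min,
            lat_cap,
        )
        L = max(
            _grade_value("length_mean", grade) + rng.uniform(-1, 1) * GRADE_PARAM_MAP["length_jitter"],
            GRADE_PARAM_MAP["length_min"],
        )
        kappa = abs(
            _grade_value("curvature_mean", grade)
            * (1.0 + rng.uniform(-1, 1) * GRADE_PARAM_MAP["curvature_jitter_frac"])
        )
        # vertical room inside the ellipse at this x
        rel = (x - cx) / tarsus.rx
        if abs(rel) >= 0.95:
            return None
        room = tarsus.ry * np.sqrt(1.0 - rel**2)
        max_len = 2.0 * (room - w_g / 2.0 - 3.0) * 0.85
        L = min(L, max_len)
        if L < 20.0:
            return None
        # split the slot's remaining lateral budget between the arc bow
        # (sagitta, centered) and the orientation tilt (end sway)
        rem = max(lat_cap - w_g, 0.0)
        if kappa * L**2 / 8.0 > rem / 2.0:
            kappa = 4.0 * rem / L**2
        sagitta = kappa * L**2 / 8.0
        shape = "arc" if kappa > 1e-4 else "straight"
        tilt_max = min(0.06, float(np.arcsin(min(rem / 2.0 / (L / 2.0), 1.0))))
        orientation = np.pi / 2.0 + rng.uniform(-1.0, 1.0) * tilt_max
        y_slack = max(room - L / 2.0 - w_g / 2.0 - sagitta, 0.0)
        y = cy + rng.uniform(-1.0, 1.0) * 0.15 * y_slack
        # center the bow laterally in its slot (the arc bulges along +normal)
        u = np.array([np.cos(orientation), np.sin(orientation)])
        nrm = np.array([-u[1], u[0]])
        anchor = np.array([x, y]) - (sagitta / 2.0) * nrm
        try:
            glands.append(
                GlandSpec(
                    anchor=(float(anchor[0]), float(anchor[1])),
                    orientation=float(orientation),
                    centerline_length=float(L),
                    width=float(w_g),
                    curvature=float(kappa),
                    shape=shape,
                )
            )
        except GenerationError:
            return None
    return glands


def generate_graded_dataset(
    n_per_grade: int,
    seed: int,
    height: int = 640,
    width: int = 1280,
) -> list[GradedSample]:
    """Seeded grade-stratified dataset: ``n_per_grade`` images per grade 0-3."""
    if n_per_grade < 1:
        raise GenerationError("n_per_grade must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[GradedSample] = []
    for grade in range(4):
        for i in range(n_per_grade):
            spec = random_image_spec(grade, rng, height=height, width=width)
            gland_mask, tarsus_mask, truth = generate_image(spec, grade=grade)
            samples.append(
                GradedSample(
                    image_id=f"g{grade}_{i:03d}",
                    gland_mask=gland_mask,
                    tarsus_mask=tarsus_mask,
                    truth=truth,
                )
            )
    return samples
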