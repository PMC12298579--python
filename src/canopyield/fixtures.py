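"""Synthetic benchmark data with exact ground truth.

Real plant-factory captures are top-down photos of a single leafy rosette
(a loose-leaf brassica) on a near-white planting board, with a ruler near
the root for scale.  No such dataset ships with this package; instead every
downstream stage is exercised on generated scenes whose foreground geometry
is an analytic union of simple shapes, so the ground-truth mask and pixel
count are exact by construction.

Three generators are provided:

* :func:`generate_canopy_scene` — one rosette (rotated ellipses around a
  central disk, pale petioles) on a noisy white board, with optional stress
  conditions that emulate the documented failure modes of colour-based
  segmentation (board-coloured petioles, shadows, over-light / over-dark
  leaf margins);
* :func:`generate_ruler_image` — a ruler strip with tick marks at a known
  mm spacing, plus helpers to measure tick runs back from the image;
* :func:`generate_yield_dataset` — an allometric area→fresh-weight table
  with multiplicative log-normal noise.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AllometryParams, CanopyScene, CapturePreset, STRESS_FLAGS

__all__ = [
    "PRESETS",
    "SIZE_CLASSES",
    "rosette_geometry",
    "rasterize_shapes",
    "generate_canopy_scene",
    "generate_ruler_image",
    "measure_tick_runs",
    "jittered_run_samples",
    "generate_yield_dataset",
    "generate_benchmark",
    "benchmark_yield_table",
]

#: Capture presets.  "overhead80cm" mirrors an 80 cm overhead smartphone capture
#: at full 6144x8192 resolution (0.078 mm/pixel); "desk1024" is the same
#: geometry downscaled 6x for desk-scale runtime, with mm_per_pixel scaled
#: accordingly so physical areas are preserved.
PRESETS = {
    "overhead80cm": CapturePreset("overhead80cm", 6144, 8192, 0.078, 80.0),
    "desk1024": CapturePreset("desk1024", 1024, 1365, 0.078 * 6144 / 1024, 80.0),
    "small512": CapturePreset("small512", 512, 512, 0.5, 80.0),
    "tiny256": CapturePreset("tiny256", 256, 256, 0.35, 80.0),
}

#: Rosette outer-radius range per growth stage, in mm (preset-independent).
SIZE_CLASSES = {
    "seedling": (18.0, 33.0),
    "mid": (42.0, 66.0),
    "mature": (70.0, 94.0),
}

#: Leaf-count range per growth stage (inclusive bounds).
_LEAF_COUNTS = {"seedling": (5, 7), "mid": (8, 11), "mature": (10, 14)}

_BOARD_BASE = 235.0
_BOARD_NOISE = 5.0


def rosette_geometry(preset: CapturePreset, size_class: str, seed: int) -> List[dict]:
    """Analytic shape list of the rosette drawn by :func:`generate_canopy_scene`.

    Returns a list of shape dicts (``kind`` in {"ellipse", "rect"}) in painter
    order.  The ground-truth mask is the union of these shapes; an external
    point-in-shape test over the same list must reproduce it exactly.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {size_class!r}; choose from {sorted(SIZE_CLASSES)}")
    rng = np.random.default_rng(seed)
    h, w = preset.image_height, preset.image_width
    lo_mm, hi_mm = SIZE_CLASSES[size_class]
    radius_mm = rng.uniform(lo_mm, hi_mm)
    radius_px = radius_mm / preset.mm_per_pixel

    jitter = 0.03 * min(h, w)
    center = (
        h / 2.0 + rng.uniform(-jitter, jitter),
        w / 2.0 + rng.uniform(-jitter, jitter),
    )
    if radius_px + jitter + 4 > min(h, w) / 2.0:
        raise ValueError(
            f"rosette of class {size_class!r} (radius {radius_px:.0f} px) does not fit "
            f"preset {preset.name!r} ({w}x{h}); use a larger preset or smaller class"
        )

    lo_n, hi_n = _LEAF_COUNTS[size_class]
    n_leaves = int(rng.integers(lo_n, hi_n + 1))

    shapes: List[dict] = []
    # petioles first (painter order: leaves drawn over them)
    leaf_params = []
    for i in range(n_leaves):
        theta = 2 * math.pi * i / n_leaves + rng.uniform(-0.12, 0.12)
        d = rng.uniform(0.55, 0.68) * radius_px
        a = radius_px - d  # tip reaches the rosette radius
        b = a * rng.uniform(0.45, 0.65)
        leaf_params.append((theta, d, a, b))
    for theta, d, a, b in leaf_params:
        shapes.append(
            {
                "kind": "rect",
                "center": (
                    center[0] + 0.5 * d * math.sin(theta),
                    center[1] + 0.5 * d * math.cos(theta),
                ),
                "length": d,
                "width": max(2.0, 0.05 * radius_px),
                "angle": theta,
                "role": "petiole",
            }
        )
    shapes.append(
        {
            "kind": "ellipse",
            "center": center,
            "axes": (0.30 * radius_px, 0.30 * radius_px),
            "angle": 0.0,
            "role": "heart",
        }
    )
    for theta, d, a, b in leaf_params:
        shapes.append(
            {
                "kind": "ellipse",
                "center": (
                    center[0] + d * math.sin(theta),
                    center[1] + d * math.cos(theta),
                ),
                "axes": (a, b),
                "angle": theta,
                "role": "leaf",
            }
        )
    return shapes


def _shape_test(shape: dict, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Vectorised membership test of pixel centres in one analytic shape."""
    cy, cx = shape["center"]
    dy = rows - cy
    dx = cols - cx
    ang = shape["angle"]
    # u: along the shape's major direction (angle measured from +col axis
    # towards +row axis), v: perpendicular.
    u = dx * math.cos(ang) + dy * math.sin(ang)
    v = -dx * math.sin(ang) + dy * math.cos(ang)
    if shape["kind"] == "ellipse":
        a, b = shape["axes"]
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if shape["kind"] == "rect":
        return (np.abs(u) <= shape["length"] / 2.0) & (np.abs(v) <= shape["width"] / 2.0)
    raise ValueError(f"unknown shape kind {shape['kind']!r}")


def _shape_bbox(shape: dict, img_shape: Tuple[int, int]) -> Tuple[int, int, int, int]:
    cy, cx = shape["center"]
    if shape["kind"] == "ellipse":
        r = max(shape["axes"]) + 1
    else:
        r = math.hypot(shape["length"], shape["width"]) / 2.0 + 1
    r0 = max(0, int(math.floor(cy - r)))
    r1 = min(img_shape[0], int(math.ceil(cy + r)) + 1)
    c0 = max(0, int(math.floor(cx - r)))
    c1 = min(img_shape[1], int(math.ceil(cx + r)) + 1)
    return r0, r1, c0, c1


def rasterize_shapes(shapes: Sequence[dict], img_shape: Tuple[int, int]) -> np.ndarray:
    """Exact union rasterization: a pixel is set iff its centre lies in a shape."""
    mask = np.zeros(img_shape, dtype=bool)
    for shape in shapes:
        r0, r1, c0, c1 = _shape_bbox(shape, img_shape)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= _shape_test(shape, rows.astype(float), cols.astype(float))
    return mask


def _paint_shape(
    image: np.ndarray, shape: dict, color: np.ndarray, rng: np.random.Generator, noise: float
) -> None:
    r0, r1, c0, c1 = _shape_bbox(shape, image.shape[:2])
    if r0 >= r1 or c0 >= c1:
        return
    rows, cols = np.mgrid[r0:r1, c0:c1]
    inside = _shape_test(shape, rows.astype(float), cols.astype(float))
    n = int(inside.sum())
    if n == 0:
        return
    pix = color[None, :] + rng.normal(0.0, noise, size=(n, 3))
    image[r0:r1, c0:c1][inside] = pix


def generate_canopy_scene(
    preset: CapturePreset,
    size_class: str,
    stress_flags: Iterable[str] = (),
    seed: int = 0,
) -> CanopyScene:
    """Render one synthetic rosette scene with its exact ground-truth mask.

    Stress flags inject the failure modes that defeat colour-based
    segmentation on real boards: ``pale_petiole`` pushes petiole colour to
    within 10 intensity units of the board, ``shadow`` multiplies a smooth
    dark gradient over part of the scene, ``light_margin`` / ``dark_margin``
    blend the outer leaf ring towards white / black.
    """
    flags = frozenset(stress_flags)
    unknown = flags - STRESS_FLAGS
    if unknown:
        raise ValueError(f"unknown stress flags: {sorted(unknown)}")
    shapes = rosette_geometry(preset, size_class, seed)
    h, w = preset.image_height, preset.image_width

    # the geometry consumed part of the seed stream; use an offset stream for
    # colours so geometry and appearance stay independently reproducible
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    image = np.empty((h, w, 3), dtype=float)
    image[...] = _BOARD_BASE
    image += rng.normal(0.0, _BOARD_NOISE, size=image.shape)

    if "pale_petiole" in flags:
        petiole_color = np.array([229.0, 233.0, 228.0])  # within 10 units of the board
    else:
        petiole_color = np.array([198.0, 214.0, 192.0])
    heart_green = rng.normal(150.0, 8.0)
    leaf_colors = {}
    for idx, shape in enumerate(shapes):
        if shape["role"] == "petiole":
            _paint_shape(image, shape, petiole_color, rng, 3.0)
        elif shape["role"] == "heart":
            color = np.array([heart_green - 75.0, heart_green, heart_green - 85.0])
            _paint_shape(image, shape, color, rng, 4.0)
        else:
            g = rng.normal(140.0, 15.0)
            color = np.array(
                [g - rng.uniform(65.0, 85.0), g, g - rng.uniform(75.0, 95.0)]
            )
            leaf_colors[idx] = color
            _paint_shape(image, shape, color, rng, 4.0)

    if flags & {"light_margin", "dark_margin"}:
        towards = 255.0 if "light_margin" in flags else 0.0
        for idx, shape in enumerate(shapes):
            if shape["role"] != "leaf":
                continue
            r0, r1, c0, c1 = _shape_bbox(shape, (h, w))
            rows, cols = np.mgrid[r0:r1, c0:c1]
            cy, cx = shape["center"]
            ang = shape["angle"]
            dy, dx = rows - cy, cols - cx
            u = dx * math.cos(ang) + dy * math.sin(ang)
            v = -dx * math.sin(ang) + dy * math.cos(ang)
            a, b = shape["axes"]
            q = (u / a) ** 2 + (v / b) ** 2
            ring = (q <= 1.0) & (q >= 0.72)
            blend = 0.75
            image[r0:r1, c0:c1][ring] = (
                (1 - blend) * image[r0:r1, c0:c1][ring] + blend * towards
            )

    if "shadow" in flags:
        # smooth multiplicative shadow lobe overlapping the rosette edge
        heart = next(s for s in shapes if s["role"] == "heart")
        cy, cx = heart["center"]
        radius_px = heart["axes"][0] / 0.30
        sy = cy + rng.uniform(0.6, 1.0) * radius_px * rng.choice([-1, 1])
        sx = cx + rng.uniform(0.6, 1.0) * radius_px * rng.choice([-1, 1])
        rows, cols = np.mgrid[0:h, 0:w]
        d2 = (rows - sy) ** 2 + (cols - sx) ** 2
        shade = 1.0 - 0.28 * np.exp(-d2 / (2 * (0.9 * radius_px) ** 2))
        image *= shade[:, :, None]

    truth_mask = rasterize_shapes(shapes, (h, w))
    image = np.clip(image, 0, 255).astype(np.uint8)
    leaf_count = sum(1 for s in shapes if s["role"] == "leaf")
    return CanopyScene(
        image=image,
        truth_mask=truth_mask,
        truth_pixel_count=int(truth_mask.sum()),
        leaf_count=leaf_count,
        stress_flags=flags,
        preset=preset,
        size_class=size_class,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ruler


def generate_ruler_image(
    preset: CapturePreset,
    tick_spacing_mm: float = 10.0,
    seed: int = 0,
    n_ticks: int = 11,
) -> Tuple[np.ndarray, float]:
    """Render a ruler strip with ticks every ``tick_spacing_mm``.

    Tick centres sit at ``round(x0 + i * tick_spacing_mm / mm_per_pixel)``
    (consistent nearest-integer rounding of the subpixel positions).  Returns
    the image and the preset's true mm-per-pixel.
    """
    if tick_spacing_mm <= 0:
        raise ValueError("tick_spacing_mm must be positive")
    interval_px = tick_spacing_mm / preset.mm_per_pixel
    if interval_px < 8:
        raise ValueError(
            f"tick spacing of {interval_px:.1f} px is below the 8 px rendering minimum"
        )
    rng = np.random.default_rng(seed)
    margin = 40
    width = int(round(interval_px * (n_ticks - 1))) + 2 * margin
    height = 100
    image = np.empty((height, width, 3), dtype=float)
    image[...] = _BOARD_BASE
    image += rng.normal(0.0, _BOARD_NOISE, size=image.shape)
    # ruler body
    image[18:82, :, :] = 215.0 + rng.normal(0.0, 2.0, size=(64, width, 3))
    for i in range(n_ticks):
        x = int(round(margin + i * interval_px))
        image[25:60, max(0, x - 1) : x + 2, :] = 30.0
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, preset.mm_per_pixel


def measure_tick_runs(image: np.ndarray) -> np.ndarray:
    """Measure adjacent tick-centre spacings (px) from a ruler image.

    Detects dark tick columns in the band containing the marks and returns
    the differences between consecutive darkness-weighted tick centroids —
    the automated analogue of drawing repeated lines along the ruler scale.
    """
    gray = np.asarray(image, dtype=float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    profile = gray[25:60, :].mean(axis=0)
    thresh = 0.5 * (profile.min() + profile.max())
    dark = profile < thresh
    if not dark.any():
        raise ValueError("no tick marks detected in ruler image")
    # group consecutive dark columns into ticks
    idx = np.flatnonzero(dark)
    splits = np.flatnonzero(np.diff(idx) > 1)
    groups = np.split(idx, splits + 1)
    centers = []
    for g in groups:
        wgt = profile[g].max() + 1.0 - profile[g]  # darker -> heavier
        centers.append(float(np.sum(g * wgt) / np.sum(wgt)))
    centers = np.asarray(centers)
    if len(centers) < 2:
        raise ValueError("need at least two ticks to measure a run")
    return np.diff(centers)


def jittered_run_samples(
    true_run_px: float,
    n: int = 30,
    jitter_px: float = 1.0,
    n_outliers: int = 0,
    outlier_factor: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Repeated manual-style measurements of one tick run.

    Emulates drawing ``n`` lines along the ruler: each sample is the true
    run plus uniform ±``jitter_px`` reading error; ``n_outliers`` gross
    mistakes at ``outlier_factor`` times the true run are appended (e.g. a
    line spanning several ticks).
    """
    if true_run_px <= 0:
        raise ValueError("true_run_px must be positive")
    rng = np.random.default_rng(seed)
    runs = true_run_px + rng.uniform(-jitter_px, jitter_px, size=n)
    if n_outliers:
        runs = np.concatenate([runs, np.full(n_outliers, outlier_factor * true_run_px)])
    return runs


# ---------------------------------------------------------------------------
# allometric yield data


def generate_yield_dataset(params: AllometryParams) -> pd.DataFrame:
    """Sample an area→fresh-weight table from the allometric model.

    ``weight = c * area**b * eps`` with ``eps`` log-normal, unit mean,
    coefficient of variation ``noise_cv``.  Areas are uniform over
    ``params.area_range_cm2`` (seedling-to-mature span).
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.area_range_cm2
    areas = rng.uniform(lo, hi, size=params.n_plants)
    weights = allometric_weights(areas, params, rng)
    return pd.DataFrame(
        {
            "plant_id": [f"plant_{i:03d}" for i in range(params.n_plants)],
            "true_area_cm2": areas,
            "fresh_weight_g": weights,
        }
    )


def allometric_weights(
    areas_cm2: np.ndarray, params: AllometryParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Apply the allometric relation (with noise) to given areas."""
    areas_cm2 = np.asarray(areas_cm2, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.noise_cv > 0:
        sigma2 = math.log(1.0 + params.noise_cv**2)
        eps = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=areas_cm2.shape)
    else:
        eps = np.ones_like(areas_cm2)
    return params.c * areas_cm2**params.b * eps


# ---------------------------------------------------------------------------
# benchmark assembly


def generate_benchmark(
    preset: CapturePreset,
    n_scenes: int = 60,
    size_classes: Sequence[str] = ("seedling", "mid", "mature"),
    stress_flags: Iterable[str] = (),
    seed: int = 42,
) -> List[CanopyScene]:
    """Generate ``n_scenes`` scenes cycling through ``size_classes``.

    Per-scene seeds are drawn from a generator seeded with ``seed``, so the
    whole benchmark is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    scenes = []
    for i in range(n_scenes):
        size_class = size_classes[i % len(size_classes)]
        scenes.append(
            generate_canopy_scene(preset, size_class, stress_flags, int(scene_seeds[i]))
        )
    return scenes


def benchmark_yield_table(scenes: Sequence[CanopyScene], params: AllometryParams) -> pd.DataFrame:
    """Fresh weights for generated scenes via the allometric relation.

    Plant ids are ``scene_{i:03d}`` and the areas are the scenes' exact
    ground-truth areas (cm²), so the table joins with per-image outputs of
    the segmentation pipeline by id.
    """
    areas = np.array([s.true_area_cm2 for s in scenes])
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    weights = allometric_weights(areas, params, rng)
    return pd.DataFrame(
        {
            "plant_id": [f"scene_{i:03d}" for i in range(len(scenes))],
            "true_area_cm2": areas,
            "fresh_weight_g": weights,
        }
    )
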