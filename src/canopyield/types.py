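"""Shared domain types.

Conventions used throughout the package:

* images are ``uint8`` (or float) arrays of shape ``(rows, cols, 3)``;
* binary masks are boolean arrays of shape ``(rows, cols)``;
* coordinates are 0-based ``(row, col)`` pairs, and a pixel occupies the
  unit square centred on its integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CapturePreset",
    "CanopyScene",
    "AllometryParams",
    "StructuringElement",
    "Contour",
    "SnakeParams",
    "SegmentationConfig",
    "MeasurementSet",
    "ScaleFactor",
    "AreaRecord",
    "ModelSpec",
    "MetricReport",
    "STRESS_FLAGS",
]

#: Recognised stress conditions for synthetic scenes.  They emulate the
#: failure modes seen in real plant-factory photos: petioles whose colour
#: nearly matches the white planting board, uneven illumination casting
#: shadows, and leaf margins that drift towards white or black.
STRESS_FLAGS = frozenset({"pale_petiole", "shadow", "light_margin", "dark_margin"})


@dataclass(frozen=True)
class CapturePreset:
    """Camera geometry of a top-down capture.

    ``mm_per_pixel`` is the ground-truth spatial resolution of the rendered
    image; ``camera_height_cm`` is metadata only (the overhead rig height).
    """

    name: str
    image_width: int
    image_height: int
    mm_per_pixel: float
    camera_height_cm: float = 80.0

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass
class CanopyScene:
    """A synthetic top-down photo of a single rosette with exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    truth_pixel_count: int
    leaf_count: int
    stress_flags: frozenset
    preset: CapturePreset
    size_class: str
    seed: int

    def __post_init__(self) -> None:
        if self.truth_mask.shape != self.image.shape[:2]:
            raise ValueError("truth_mask shape must match image shape")
        if self.truth_pixel_count != int(self.truth_mask.sum()):
            raise ValueError("truth_pixel_count inconsistent with truth_mask")
        if self.leaf_count < 1:
            raise ValueError("leaf_count must be >= 1")
        unknown = set(self.stress_flags) - set(STRESS_FLAGS)
        if unknown:
            raise ValueError(f"unknown stress flags: {sorted(unknown)}")

    @property
    def true_area_mm2(self) -> float:
        return self.truth_pixel_count * self.preset.mm_per_pixel**2

    @property
    def true_area_cm2(self) -> float:
        return self.true_area_mm2 / 100.0


@dataclass(frozen=True)
class AllometryParams:
    """Power-law area→fresh-weight relation with multiplicative noise.

    ``weight = c * area**b * eps`` with ``eps`` log-normal of coefficient of
    variation ``noise_cv``.  ``c`` is in g per cm^(2b), ``b`` dimensionless.
    """

    c: float = 0.9
    b: float = 1.15
    noise_cv: float = 0.12
    n_plants: int = 60
    seed: int = 0
    area_range_cm2: tuple = (60.0, 200.0)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.b <= 0:
            raise ValueError("allometry c and b must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_plants < 2:
            raise ValueError("n_plants must be >= 2")


@dataclass(frozen=True)
class StructuringElement:
    """Small binary template with an explicit origin.

    The origin is the cell that gets aligned with the probed image pixel when
    the element is translated; it must lie inside the grid.
    """

    grid: np.ndarray
    origin: tuple

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        r, c = self.origin
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            raise ValueError("origin must lie inside the grid")
        if not grid.any():
            raise ValueError("structuring element must have at least one true cell")

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of (drow, dcol) offsets of true cells relative to origin."""
        rows, cols = np.nonzero(self.grid)
        return np.stack([rows - self.origin[0], cols - self.origin[1]], axis=1)

    def reflect(self) -> "StructuringElement":
        """Point reflection about the origin (for the erosion/dilation duality)."""
        grid = self.grid[::-1, ::-1].copy()
        origin = (self.grid.shape[0] - 1 - self.origin[0], self.grid.shape[1] - 1 - self.origin[1])
        return StructuringElement(grid, origin)

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        if radius < 1:
            raise ValueError("disk radius must be >= 1")
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        return cls(yy**2 + xx**2 <= radius**2, (radius, radius))

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        if size < 1:
            raise ValueError("square size must be >= 1")
        return cls(np.ones((size, size), dtype=bool), (size // 2, size // 2))


@dataclass
class Contour:
    """Closed contour as an ordered list of subpixel (row, col) vertices."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 (row, col) vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def spacings(self) -> np.ndarray:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return np.hypot(d[:, 0], d[:, 1])


@dataclass(frozen=True)
class SnakeParams:
    """Active-contour evolution parameters.

    alpha      elasticity (first-derivative) weight, >= 0
    beta       rigidity (second-derivative) weight, >= 0
    gamma      evolution step size, > 0
    sigma      Gaussian pre-smoothing scale of the grayscale image, px
    max_iter   iteration cap
    tol        convergence threshold: mean net vertex displacement across a
               10-iteration window, px
    target_spacing / max_vertices: the contour is resampled to roughly
               uniform arc length; vertex count = clip(perimeter/spacing).
    """

    alpha: float = 0.2
    beta: float = 0.5
    gamma: float = 1.0
    sigma: float = 5.0
    max_iter: int = 500
    tol: float = 0.1
    target_spacing: float = 1.2
    max_vertices: int = 1000

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class SegmentationConfig:
    """End-to-end segmentation configuration."""

    color_threshold_mode: str = "otsu"
    fixed_threshold: Optional[float] = None
    se_radius: int = 5
    min_component_fraction: float = 0.5
    snake: SnakeParams = field(default_factory=SnakeParams)
    working_long_side: int = 1024
    min_class_separation: float = 40.0

    def __post_init__(self) -> None:
        if self.color_threshold_mode not in ("otsu", "fixed"):
            raise ValueError("color_threshold_mode must be 'otsu' or 'fixed'")
        if self.color_threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        if self.se_radius < 1:
            raise ValueError("se_radius must be >= 1")
        if not (0 < self.min_component_fraction < 1):
            raise ValueError("min_component_fraction must be in (0, 1)")


@dataclass(frozen=True)
class MeasurementSet:
    """Repeated pixel-length measurements of one known physical span."""

    physical_length_mm: float
    pixel_runs: tuple

    def __post_init__(self) -> None:
        if self.physical_length_mm <= 0:
            raise ValueError("physical length must be positive")
        runs = tuple(float(r) for r in self.pixel_runs)
        if len(runs) < 1:
            raise ValueError("need at least one pixel run")
        if any(r <= 0 for r in runs):
            raise ValueError("pixel runs must be positive")
        object.__setattr__(self, "pixel_runs", runs)


@dataclass(frozen=True)
class ScaleFactor:
    """Ruler factor k (mm per pixel) with cleaning provenance."""

    k: float
    n_used: int
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_used < 1:
            raise ValueError("n_used must be >= 1")


@dataclass(frozen=True)
class AreaRecord:
    """One plant's pixel count and its calibrated physical area."""

    plant_id: str
    s_pixel: int
    s_recog_mm2: float

    @property
    def s_recog_cm2(self) -> float:
        return self.s_recog_mm2 / 100.0


@dataclass(frozen=True)
class ModelSpec:
    """One registry entry of the 28-model comparison."""

    model_id: str
    family: str
    variant_name: str
    interpretability: str
    hyperparameters: tuple = ()

    @property
    def hyper_dict(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class MetricReport:
    """Eight-metric evaluation of one fitted model on held-out data."""

    model_id: str
    mae: float
    mape: float
    mse: float
    rmse: float
    r2: float
    prediction_speed: float
    training_time: float
    model_size: int

    METRIC_NAMES = (
        "mae",
        "mape",
        "mse",
        "rmse",
        "r2",
        "prediction_speed",
        "training_time",
        "model_size",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}
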