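"""Canopy extraction: colour features, morphological refinement, snake contour.

The chain mirrors how the physical scenes are structured — green vegetation
on a near-white planting board — and proceeds in four stages:

1. :func:`color_segment`: excess-green index 2G − R − B, thresholded (Otsu
   by default);
2. :func:`refine_mask`: closing with a disk, exact hole filling, largest
   connected component;
3. :func:`snake_evolve` (see :mod:`canopyield.snake`) initialised on the
   morphological boundary;
4. :func:`contour_to_mask`: even-odd polygon rasterisation of the refined
   contour.

:func:`segment_canopy` runs the full chain, optionally at a reduced working
resolution, and always reports the pixel count at native resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage as ndi
from skimage import measure, transform
from skimage.filters import threshold_otsu

from .morphology import close
from .snake import SnakeError, snake_evolve
from .types import Contour, SegmentationConfig, StructuringElement

__all__ = [
    "SegmentationError",
    "NoPlantFoundError",
    "excess_green",
    "color_segment",
    "refine_mask",
    "boundary_contour",
    "contour_to_mask",
    "segment_canopy",
    "SegmentationResult",
]

logger = logging.getLogger(__name__)

_CROSS4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE8 = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    pass


class NoPlantFoundError(SegmentationError):
    """No separable green foreground in the image."""


def excess_green(image: np.ndarray) -> np.ndarray:
    """Excess-green index 2G − R − B on a 0–255 intensity scale."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    if img.max() <= 1.0:
        img = img * 255.0
    return 2.0 * img[..., 1] - img[..., 0] - img[..., 2]


def _separation(exg: np.ndarray, thr: float) -> float:
    mask = exg > thr
    if not mask.any() or mask.all():
        return 0.0
    return float(exg[mask].mean() - exg[~mask].mean())


def color_segment(image: np.ndarray, config: Optional[SegmentationConfig] = None) -> np.ndarray:
    """Threshold the excess-green index into a vegetation mask.

    Raises :class:`NoPlantFoundError` when the index field is constant or
    when the thresholded classes are not separated by at least
    ``config.min_class_separation`` index units (an all-board image splits
    its own sensor noise, with class means only a few units apart).
    """
    if config is None:
        config = SegmentationConfig()
    exg = excess_green(image)
    if np.ptp(exg) == 0:
        raise NoPlantFoundError("constant excess-green field: no separable foreground")
    if config.color_threshold_mode == "fixed":
        thr = float(config.fixed_threshold)
    else:
        thr = float(threshold_otsu(exg))
        # when the canopy covers a tiny fraction of the board, Otsu's
        # between-class variance can peak inside the broad background mode;
        # a second pass restricted to the upper class recovers the true
        # board/vegetation split (hierarchical Otsu)
        if _separation(exg, thr) < config.min_class_separation:
            upper = exg[exg > thr]
            if upper.size > 1 and np.ptp(upper) > 0:
                thr = float(threshold_otsu(upper))
    mask = exg > thr
    if not mask.any() or mask.all():
        raise NoPlantFoundError("thresholding produced an empty class")
    separation = exg[mask].mean() - exg[~mask].mean()
    if separation < config.min_class_separation:
        raise NoPlantFoundError(
            f"foreground/background excess-green separation {separation:.1f} "
            f"below {config.min_class_separation}: no plant found"
        )
    return mask


def refine_mask(mask: np.ndarray, config: Optional[SegmentationConfig] = None) -> np.ndarray:
    """Morphological cleanup: closing, hole fill, largest component.

    Holes are background regions not 4-connected to the image border —
    filled exactly rather than by repeated closings.  The largest
    8-connected foreground component is kept alone when it holds at least
    ``min_component_fraction`` of the foreground.
    """
    if config is None:
        config = SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoPlantFoundError("empty mask: no plant found")
    closed = close(mask, StructuringElement.disk(config.se_radius))

    background = ~closed
    labels, _ = ndi.label(background, structure=_CROSS4)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    filled = closed | (background & ~np.isin(labels, border_labels))

    comp, n_comp = ndi.label(filled, structure=_SQUARE8)
    if n_comp > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        largest = int(sizes.argmax())
        if sizes[largest] >= config.min_component_fraction * sizes.sum():
            filled = comp == largest
        else:
            logger.info(
                "largest component holds %.0f%% of foreground; keeping all components",
                100 * sizes[largest] / sizes.sum(),
            )
    return filled


def boundary_contour(mask: np.ndarray) -> Contour:
    """Longest closed iso-contour of the mask (subpixel, at level 0.5)."""
    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise NoPlantFoundError("mask has no boundary contour")
    best = max(contours, key=lambda c: np.hypot(*np.diff(c, axis=0).T).sum())
    if np.allclose(best[0], best[-1]):
        best = best[:-1]
    if len(best) < 3:
        raise NoPlantFoundError("degenerate boundary contour")
    return Contour(best)


def contour_to_mask(contour: Contour, shape: Tuple[int, int]) -> np.ndarray:
    """Rasterise a closed contour: pixel set iff its centre is inside or on
    the polygon under the even-odd rule.

    A self-intersecting polygon is still filled (even-odd), with a logged
    warning.
    """
    verts = np.asarray(contour.vertices, dtype=float)
    _warn_if_self_intersecting(verts)
    mask = np.zeros(shape, dtype=bool)
    r0 = max(0, int(np.floor(verts[:, 0].min())))
    r1 = min(shape[0], int(np.ceil(verts[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(verts[:, 1].min())))
    c1 = min(shape[1], int(np.ceil(verts[:, 1].max())) + 1)
    if r0 >= r1 or c0 >= c1:
        return mask
    rows, cols = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    path = MplPath(np.vstack([verts, verts[:1]]), closed=True)
    # boundary-inclusive: a tiny expansion on either orientation keeps
    # points that lie exactly on an edge, independent of traversal order
    inside = path.contains_points(pts, radius=1e-9) | path.contains_points(
        pts, radius=-1e-9
    )
    mask[r0:r1, c0:c1] = inside.reshape(rows.shape)
    return mask


def _warn_if_self_intersecting(verts: np.ndarray) -> None:
    if len(verts) > 2000:  # validity check is quadratic-ish; skip huge contours
        return
    try:
        from shapely.geometry import Polygon

        if not Polygon(np.c_[verts[:, 1], verts[:, 0]]).is_valid:
            logger.warning("self-intersecting contour; applying even-odd fill anyway")
    except Exception:  # pragma: no cover - shapely hiccups are non-fatal
        pass


@dataclass
class SegmentationResult:
    mask: np.ndarray
    contour: Contour
    pixel_count: int
    converged: bool
    iterations: int
    fallback_used: bool

    def __iter__(self):
        # allows ``mask, contour, count = segment_canopy(...)``
        return iter((self.mask, self.contour, self.pixel_count))


def segment_canopy(
    image: np.ndarray, config: Optional[SegmentationConfig] = None
) -> SegmentationResult:
    """Full chain: colour threshold → morphology → snake → polygon mask.

    If the image's long side exceeds ``config.working_long_side`` the chain
    runs at reduced scale and the final mask is resized back to native
    resolution (nearest neighbour); the pixel count is always taken at
    native resolution.  A snake failure falls back to the morphological
    mask with a logged warning.
    """
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    native_shape = image.shape[:2]
    long_side = max(native_shape)
    if long_side > config.working_long_side:
        scale = config.working_long_side / long_side
        work_shape = (
            int(round(native_shape[0] * scale)),
            int(round(native_shape[1] * scale)),
        )
        work_img = transform.resize(
            image, work_shape, anti_aliasing=True, preserve_range=True
        )
    else:
        scale = 1.0
        work_shape = native_shape
        work_img = image

    color_mask = color_segment(work_img, config)
    morph_mask = refine_mask(color_mask, config)
    init = boundary_contour(morph_mask)

    fallback = False
    converged = False
    iterations = 0
    try:
        result = snake_evolve(work_img, init, config.snake)
        converged, iterations = result.converged, result.iterations
        contour = result.contour
        work_mask = contour_to_mask(contour, work_shape)
        if not work_mask.any():
            raise SnakeError("snake contour rasterised to an empty mask")
    except SnakeError as exc:
        logger.warning("snake refinement failed (%s); using morphological mask", exc)
        fallback = True
        contour = init
        work_mask = morph_mask

    if scale != 1.0:
        final = (
            transform.resize(
                work_mask.astype(float), native_shape, order=0, anti_aliasing=False
            )
            > 0.5
        )
        contour = Contour(contour.vertices / scale)
    else:
        final = work_mask

    return SegmentationResult(
        mask=final,
        contour=contour,
        pixel_count=int(final.sum()),
        converged=converged,
        iterations=iterations,
        fallback_used=fallback,
    )
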