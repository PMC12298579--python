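"""Ruler calibration and pixel→area conversion.

The ruler factor k (mm per pixel) comes from repeated pixel-length
measurements of a known physical span: the measurements are cleaned with
the 1.5×IQR fence, averaged, and divided into the physical length,
k = L_recog / mean(L_pixel).  Because area scales with the square of
length, a pixel count S_pixel converts to physical area as
S_recog = k² · S_pixel (mm²).

Mask fidelity against ground truth is quantified by an ordinary
least-squares regression of recovered pixel counts on true pixel counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .types import MeasurementSet, ScaleFactor

__all__ = [
    "iqr_clean",
    "estimate_scale",
    "pixels_to_area",
    "mask_fidelity_regression",
    "FidelityRegression",
]

logger = logging.getLogger(__name__)


def iqr_clean(values: Sequence[float]) -> Tuple[list, list]:
    """Split values into (kept, rejected) by the 1.5×IQR fence.

    Quartiles use linear interpolation between order statistics.  Fewer
    than four values are returned unchanged (quartiles of so few points
    are not meaningful), with a logged notice.  Order is preserved within
    each output list.
    """
    vals = [float(v) for v in values]
    if len(vals) == 0:
        raise ValueError("cannot clean an empty list")
    if len(vals) < 4:
        logger.info("only %d values: IQR cleaning skipped", len(vals))
        return vals, []
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in vals if lo <= v <= hi]
    rejected = [v for v in vals if not (lo <= v <= hi)]
    return kept, rejected


def estimate_scale(ms: MeasurementSet) -> ScaleFactor:
    """Ruler factor k = L_recog / mean(cleaned pixel runs), in mm/pixel."""
    kept, rejected = iqr_clean(ms.pixel_runs)
    if not kept:  # unreachable with the fence definition; guarded anyway
        raise ValueError("all pixel-run samples rejected by IQR cleaning")
    k = ms.physical_length_mm / float(np.mean(kept))
    return ScaleFactor(k=k, n_used=len(kept), n_rejected=len(rejected))


def pixels_to_area(s_pixel: int, k: ScaleFactor | float) -> float:
    """Physical area in mm² of ``s_pixel`` foreground pixels: k² · S_pixel."""
    if s_pixel < 0:
        raise ValueError("pixel count must be non-negative")
    kval = k.k if isinstance(k, ScaleFactor) else float(k)
    return kval**2 * s_pixel


@dataclass(frozen=True)
class FidelityRegression:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray


def mask_fidelity_regression(
    pred_counts: Sequence[float], truth_counts: Sequence[float]
) -> FidelityRegression:
    """OLS of recovered pixel counts on ground-truth counts.

    Truth is the reference (x axis); residuals are returned for
    distributional inspection.
    """
    pred = np.asarray(pred_counts, dtype=float)
    truth = np.asarray(truth_counts, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(truth) == 0:
        raise ValueError("truth counts are all equal: regression undefined")
    if np.ptp(pred) == 0:
        # constant predictions explain nothing: flat fit, R^2 = 0
        return FidelityRegression(
            slope=0.0,
            intercept=float(pred[0]),
            r_squared=0.0,
            residuals=np.zeros_like(pred),
        )
    fit = stats.linregress(truth, pred)
    residuals = pred - (fit.slope * truth + fit.intercept)
    return FidelityRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residuals=residuals,
    )
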