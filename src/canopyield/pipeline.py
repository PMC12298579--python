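"""End-to-end orchestration: images → masks → areas → model comparison.

:func:`run_pipeline` executes the whole analysis from a :class:`RunConfig`:
segment every image, calibrate the mm-per-pixel factor (from a ruler image,
a measurement CSV, or a precomputed k), convert pixel counts to physical
areas, join with the fresh-weight table by plant id (image file stem), run
the 28-model comparison, and write the artifact bundle.  All randomness
flows from the single config seed, and inputs are never mutated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import calibration, fixtures, segmentation, yield_models
from .types import MeasurementSet, ScaleFactor, SegmentationConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_scale_source"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs and knobs of one end-to-end run.

    Exactly one calibration source must be set: ``ruler_image`` (+
    ``ruler_length_mm``), ``measurements_csv`` (+ ``ruler_length_mm``), or
    ``k_mm_per_pixel``.
    """

    images_dir: Path
    weights_csv: Path
    out_dir: Path
    ruler_image: Optional[Path] = None
    measurements_csv: Optional[Path] = None
    ruler_length_mm: Optional[float] = None
    k_mm_per_pixel: Optional[float] = None
    truth_masks_dir: Optional[Path] = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    split_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [
            self.ruler_image is not None,
            self.measurements_csv is not None,
            self.k_mm_per_pixel is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one calibration source required: ruler image, "
                "measurement CSV, or precomputed k"
            )
        if (self.ruler_image or self.measurements_csv) and self.ruler_length_mm is None:
            raise ValueError("ruler_length_mm required with a ruler image or measurement CSV")
        for attr in ("images_dir", "weights_csv", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))


def load_scale_source(config: RunConfig) -> ScaleFactor:
    """Resolve the calibration source into a ScaleFactor."""
    if config.k_mm_per_pixel is not None:
        return ScaleFactor(k=float(config.k_mm_per_pixel), n_used=1, n_rejected=0)
    if config.ruler_image is not None:
        image = np.asarray(Image.open(config.ruler_image))
        runs = fixtures.measure_tick_runs(image)
    else:
        runs = pd.read_csv(config.measurements_csv)["run_px"].to_numpy(dtype=float)
    return calibration.estimate_scale(
        MeasurementSet(physical_length_mm=config.ruler_length_mm, pixel_runs=tuple(runs))
    )


_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis and write the artifact bundle to ``out_dir``.

    Returns the bundle as a dict; identical config + seed gives identical
    numeric outputs.
    """
    images = sorted(
        p for p in Path(config.images_dir).iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not images:
        raise PipelineError(f"no images found in {config.images_dir}")
    weights = pd.read_csv(config.weights_csv)
    if not {"plant_id", "fresh_weight_g"} <= set(weights.columns):
        raise PipelineError("weights CSV needs columns plant_id, fresh_weight_g")
    weights = weights.set_index("plant_id")

    stems = [p.stem for p in images]
    missing = sorted(set(stems) - set(weights.index.astype(str)))
    extra = sorted(set(weights.index.astype(str)) - set(stems))
    if missing or extra:
        raise PipelineError(
            f"unmatched plant ids between images and weights: "
            f"images without weights {missing}; weights without images {extra}"
        )

    out = Path(config.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    scale = load_scale_source(config)
    seg_rows: List[dict] = []
    failures: List[str] = []
    truth_counts: Dict[str, int] = {}
    for path in images:
        image = np.asarray(Image.open(path).convert("RGB"))
        try:
            result = segmentation.segment_canopy(image, config.segmentation)
        except segmentation.SegmentationError as exc:
            logger.warning("segmentation failed for %s: %s", path.name, exc)
            failures.append(path.stem)
            continue
        area_mm2 = calibration.pixels_to_area(result.pixel_count, scale)
        seg_rows.append(
            {
                "plant_id": path.stem,
                "Spixel": result.pixel_count,
                "Srecog_mm2": area_mm2,
                "Srecog_cm2": area_mm2 / 100.0,
                "converged": result.converged,
                "iterations": result.iterations,
                "fallback_used": result.fallback_used,
            }
        )
        Image.fromarray(result.mask.astype(np.uint8) * 255).save(
            out / "masks" / f"{path.stem}.png"
        )
        if config.truth_masks_dir is not None:
            tpath = Path(config.truth_masks_dir) / f"{path.stem}.png"
            if tpath.exists():
                tmask = np.asarray(Image.open(tpath).convert("L")) > 127
                truth_counts[path.stem] = int(tmask.sum())

    if not seg_rows:
        raise PipelineError("segmentation failed for every image")
    areas = pd.DataFrame(seg_rows)
    areas.to_csv(out / "areas.csv", index=False)

    fidelity = None
    matched = [r for r in seg_rows if r["plant_id"] in truth_counts]
    if len(matched) >= 3:
        fit = calibration.mask_fidelity_regression(
            [r["Spixel"] for r in matched],
            [truth_counts[r["plant_id"]] for r in matched],
        )
        fidelity = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n": len(matched),
        }
        (out / "fidelity.json").write_text(json.dumps(fidelity, indent=2))

    joined = areas.merge(
        weights.reset_index().assign(plant_id=lambda d: d.plant_id.astype(str)),
        on="plant_id",
    )
    records = yield_models.records_from_arrays(
        joined["Srecog_cm2"], joined["fresh_weight_g"]
    )
    comparison = yield_models.compare_models(
        records, fraction=config.split_fraction, seed=config.seed
    )
    metrics = comparison.metrics_frame
    metrics.to_csv(out / "metrics.csv")
    comparison.normalized.to_csv(out / "normalized_metrics.csv")

    bundle = {
        "seed": config.seed,
        "n_images": len(images),
        "n_segmented": len(seg_rows),
        "segmentation_failures": failures,
        "scale": {"k_mm_per_pixel": scale.k, "n_used": scale.n_used, "n_rejected": scale.n_rejected},
        "fidelity": fidelity,
        "selected_model": comparison.selected,
        "top4": comparison.top4,
        "composite_scores": comparison.composite_scores,
        "out_dir": str(out),
        "defaults": {
            "segmentation": dataclasses.asdict(config.segmentation),
            "split_fraction": config.split_fraction,
        },
    }
    (out / "comparison.json").write_text(
        json.dumps(
            {
                **{k: v for k, v in bundle.items() if k != "defaults"},
                "radar": comparison.radar.to_dict(),
            },
            indent=2,
            default=str,
        )
    )
    logger.info(
        "pipeline done: %d/%d images segmented, k=%.4f mm/px, selected %s",
        len(seg_rows), len(images), scale.k, comparison.selected,
    )
    # keep in-memory handles for report generation
    bundle["_comparison"] = comparison
    bundle["_records"] = records
    return bundle
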