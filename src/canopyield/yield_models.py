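"""Fresh-weight prediction benchmarking.

Fits the 28 registry configurations to (canopy area, fresh weight) records,
scores each on a held-out validation split with eight metrics — MAE, MAPE,
MSE, RMSE, R², prediction speed, training time, model size — min–max
normalises the metric matrix, and selects a model by the top-4/composite
procedure: the four highest-R² models are re-normalised among themselves
and the one with the best mean normalised score wins.
"""

from __future__ import annotations

import logging
import pickle
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .registry import build_estimator, model_registry
from .types import MetricReport, ModelSpec

__all__ = [
    "records_from_arrays",
    "split_holdout",
    "fit_model",
    "evaluate_model",
    "normalize_metrics",
    "rank_models",
    "compare_models",
    "reports_to_frame",
    "fit_allometry",
    "FittedModel",
    "ComparisonReport",
]

logger = logging.getLogger(__name__)

#: metrics where larger is better; all others are inverted when normalising
_HIGHER_BETTER = {"r2", "prediction_speed"}

AREA_COL = "area_cm2"
WEIGHT_COL = "fresh_weight_g"


def records_from_arrays(areas: Sequence[float], weights: Sequence[float]) -> pd.DataFrame:
    """Build the canonical record table from parallel area/weight arrays."""
    areas = np.asarray(areas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if areas.shape != weights.shape:
        raise ValueError("areas and weights must have equal length")
    return pd.DataFrame({AREA_COL: areas, WEIGHT_COL: weights})


def split_holdout(
    records: pd.DataFrame, fraction: float = 0.25, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic shuffled holdout split; validation share = ``fraction``."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = len(records)
    if n < 8:
        raise ValueError(f"need at least 8 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(n * fraction))
    n_val = min(max(n_val, 1), n - 1)
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    return records.iloc[train_idx].reset_index(drop=True), records.iloc[
        val_idx
    ].reset_index(drop=True)


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    training_time: float
    model_size: int

    def predict(self, areas: Sequence[float]) -> np.ndarray:
        X = np.asarray(areas, dtype=float).reshape(-1, 1)
        return np.asarray(self.estimator.predict(X), dtype=float).ravel()


def fit_model(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit one registry configuration; records wall-clock time and pickled size."""
    if len(train) == 0:
        raise ValueError("empty training set")
    X = train[AREA_COL].to_numpy().reshape(-1, 1)
    y = train[WEIGHT_COL].to_numpy()
    estimator = build_estimator(spec)
    t0 = time.perf_counter()
    try:
        estimator.fit(X, y)
    except Exception as exc:
        raise RuntimeError(
            f"fit failed for {spec.variant_name} ({spec.family}): {exc}"
        ) from exc
    elapsed = time.perf_counter() - t0
    size = len(pickle.dumps(estimator))
    return FittedModel(spec=spec, estimator=estimator, training_time=elapsed, model_size=size)


def evaluate_model(model: FittedModel, validation: pd.DataFrame) -> MetricReport:
    """Eight-metric evaluation on held-out records.

    MAE = mean|y−ŷ|, MAPE = 100·mean(|y−ŷ|/y), MSE = mean (y−ŷ)²,
    RMSE = √MSE, R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)².  Prediction speed is measured
    (observations per second of wall time), never asserted.
    """
    if len(validation) == 0:
        raise ValueError("empty validation set")
    y = validation[WEIGHT_COL].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("MAPE undefined: all weights must be positive")
    areas = validation[AREA_COL].to_numpy(dtype=float)

    # repeat prediction until it takes a measurable slice of wall time
    reps, elapsed = 0, 0.0
    t0 = time.perf_counter()
    while elapsed < 1e-3:
        yhat = model.predict(areas)
        reps += 1
        elapsed = time.perf_counter() - t0
    speed = reps * len(y) / elapsed

    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err) / y))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
    return MetricReport(
        model_id=model.spec.model_id,
        mae=mae,
        mape=mape,
        mse=mse,
        rmse=rmse,
        r2=r2,
        prediction_speed=speed,
        training_time=model.training_time,
        model_size=model.model_size,
    )


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    frame = pd.DataFrame([r.as_dict() for r in reports], index=[r.model_id for r in reports])
    frame.index.name = "model_id"
    return frame


def normalize_metrics(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Min–max normalise the metric matrix to [0, 1] with 1 = best.

    Error metrics, training time and model size are inverted; R² and
    prediction speed map directly.  A constant column maps to all zeros.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to normalise")
    frame = reports_to_frame(reports)
    out = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        span = v.max() - v.min()
        if span == 0:
            out[col] = 0.0
            continue
        scaled = (v - v.min()) / span
        out[col] = scaled if col in _HIGHER_BETTER else 1.0 - scaled
    return out


@dataclass
class ComparisonReport:
    reports: List[MetricReport]
    normalized: pd.DataFrame
    top4: List[str]
    composite_scores: Dict[str, float]
    selected: str
    radar: pd.DataFrame = field(repr=False, default=None)

    @property
    def metrics_frame(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)


def rank_models(reports: Sequence[MetricReport]) -> ComparisonReport:
    """Top-4-by-R² selection with composite normalised scoring.

    The four highest-R² models (ties broken by lower RMSE) are min–max
    normalised among themselves across all eight metrics; the composite
    score is the row mean and the highest composite wins (ties broken by
    higher R²).  The top-4 normalised matrix doubles as radar-chart data.
    """
    if len(reports) < 4:
        raise ValueError("need at least 4 reports to rank")
    by_id = {r.model_id: r for r in reports}
    ordered = sorted(reports, key=lambda r: (-r.r2, r.rmse))
    top4 = [r.model_id for r in ordered[:4]]
    radar = normalize_metrics([by_id[mid] for mid in top4])
    composite = {mid: float(radar.loc[mid].mean()) for mid in top4}
    selected = max(top4, key=lambda mid: (composite[mid], by_id[mid].r2))
    return ComparisonReport(
        reports=list(reports),
        normalized=normalize_metrics(reports),
        top4=top4,
        composite_scores=composite,
        selected=selected,
        radar=radar,
    )


def compare_models(
    records: pd.DataFrame,
    fraction: float = 0.25,
    seed: int = 0,
    model_ids: Optional[Sequence[str]] = None,
) -> ComparisonReport:
    """Fit and rank the registry on one holdout split of ``records``."""
    train, validation = split_holdout(records, fraction, seed)
    specs = model_registry()
    if model_ids is not None:
        wanted = set(model_ids)
        specs = [s for s in specs if s.model_id in wanted]
        missing = wanted - {s.model_id for s in specs}
        if missing:
            raise ValueError(f"unknown model ids: {sorted(missing)}")
    reports = []
    for spec in specs:
        fitted = fit_model(spec, train)
        reports.append(evaluate_model(fitted, validation))
    return rank_models(reports)


def fit_allometry(
    areas_cm2: Sequence[float], weights_g: Sequence[float]
) -> Tuple[float, float]:
    """Recover (c, b) of weight = c · area^b by OLS on the log–log scale."""
    a = np.asarray(areas_cm2, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if (a <= 0).any() or (w <= 0).any():
        raise ValueError("areas and weights must be positive for a log-log fit")
    fit = stats.linregress(np.log(a), np.log(w))
    return float(np.exp(fit.intercept)), float(fit.slope)
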