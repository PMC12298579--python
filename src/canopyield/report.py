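"""Human-readable summary figures for a pipeline bundle.

Renders three panels into the bundle's output directory: per-model metric
bars, a radar chart of the normalised metrics for the four highest-R²
models, and a predicted-vs-observed scatter (with OLS fit line) for the
selected model.  Regeneration is idempotent.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import MetricReport
from .yield_models import compare_models, fit_model, split_holdout
from .registry import model_registry

__all__ = ["make_report"]

_REQUIRED = ("_comparison", "_records", "out_dir", "selected_model", "seed")


def make_report(bundle: Dict) -> Dict[str, Path]:
    """Render metric bars, radar chart and fit scatter; returns figure paths."""
    missing = [k for k in _REQUIRED if k not in bundle]
    if missing:
        raise ValueError(f"bundle is missing members: {missing}")
    out = Path(bundle["out_dir"]) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    comparison = bundle["_comparison"]
    paths = {}

    # --- metric bar panels ------------------------------------------------
    frame = comparison.metrics_frame
    fig, axes = plt.subplots(4, 2, figsize=(13, 14))
    for ax, col in zip(axes.ravel(), MetricReport.METRIC_NAMES):
        ax.bar(frame.index, frame[col], color="seagreen")
        ax.set_title(col.upper() if len(col) <= 4 else col.replace("_", " "))
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.suptitle("Per-model performance metrics")
    fig.tight_layout()
    paths["metrics"] = out / "metric_panels.png"
    fig.savefig(paths["metrics"], dpi=120)
    plt.close(fig)

    # --- radar chart of top-4 normalised metrics --------------------------
    radar = comparison.radar
    labels = list(radar.columns)
    angles = np.linspace(0, 2 * math.pi, len(labels), endpoint=False).tolist()
    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(polar=True)
    for mid in radar.index:
        vals = radar.loc[mid].tolist()
        ax.plot(angles + angles[:1], vals + vals[:1], label=mid)
        ax.fill(angles + angles[:1], vals + vals[:1], alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylim(0, 1)
    ax.set_title("Normalised metrics, top-4 models")
    ax.legend(loc="lower right", fontsize=8)
    paths["radar"] = out / "radar.png"
    fig.savefig(paths["radar"], dpi=120)
    plt.close(fig)

    # --- predicted vs observed for the selected model ----------------------
    records = bundle["_records"]
    train, val = split_holdout(records, bundle.get("split_fraction", 0.25), bundle["seed"])
    spec = next(s for s in model_registry() if s.model_id == bundle["selected_model"])
    fitted = fit_model(spec, train)
    y = val["fresh_weight_g"].to_numpy()
    yhat = fitted.predict(val["area_cm2"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(y, yhat, color="seagreen", alpha=0.8)
    coeffs = np.polyfit(y, yhat, 1)
    span = np.array([y.min(), y.max()])
    ax.plot(span, np.polyval(coeffs, span), "k--", label=f"fit y={coeffs[0]:.2f}x+{coeffs[1]:.1f}")
    ax.plot(span, span, color="gray", lw=0.8, label="1:1")
    ax.set_xlabel("observed fresh weight (g)")
    ax.set_ylabel("predicted fresh weight (g)")
    ax.set_title(f"{spec.variant_name} ({spec.model_id}) on validation split")
    ax.legend()
    paths["scatter"] = out / "selected_model_fit.png"
    fig.savefig(paths["scatter"], dpi=120)
    plt.close(fig)
    return paths
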