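#!/usr/bin/env python
"""Benchmark the 28 regression configurations on the recovered canopy areas.

Joins the recovered pixel counts (02) with the calibrated scale factor (03)
and the benchmark fresh weights (01), fits all 28 registry models on a 75/25
holdout split, scores the eight metrics, and applies the top-4/composite
selection.  Writes metrics.csv, normalized_metrics.csv and comparison.json
under results/, and the radar chart under results/figures/.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from canopyield.calibration import pixels_to_area
from canopyield.registry import model_registry
from canopyield.yield_models import compare_models, records_from_arrays

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--split", type=float, default=0.25)
    args = parser.parse_args()

    results = ROOT / "results"
    try:
        counts = pd.read_csv(results / "recovered_counts.csv")
        truth = pd.read_csv(results / "benchmark_truth.csv")
        k = json.loads((results / "calibration.json").read_text())["true_mm_per_pixel"]
    except FileNotFoundError as exc:
        raise SystemExit(f"missing input ({exc.filename}); run analyses 01-03 first")

    # desk-scale preset: same physical geometry at 6x coarser pixels
    k_desk = k * 6144 / 1024
    merged = counts.merge(truth[["plant_id", "fresh_weight_g"]], on="plant_id")
    areas_cm2 = np.array(
        [pixels_to_area(c, k_desk) / 100.0 for c in merged.recovered_pixel_count]
    )
    records = records_from_arrays(areas_cm2, merged.fresh_weight_g)

    comparison = compare_models(records, fraction=args.split, seed=args.seed)
    frame = comparison.metrics_frame
    frame.to_csv(results / "metrics.csv")
    comparison.normalized.to_csv(results / "normalized_metrics.csv")
    names = {s.model_id: s.variant_name for s in model_registry()}
    (results / "comparison.json").write_text(
        json.dumps(
            {
                "seed": args.seed,
                "split_fraction": args.split,
                "top4": comparison.top4,
                "top4_names": [names[m] for m in comparison.top4],
                "composite_scores": comparison.composite_scores,
                "selected": comparison.selected,
                "selected_name": names[comparison.selected],
            },
            indent=2,
        )
    )

    figdir = results / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    radar = comparison.radar
    angles = np.linspace(0, 2 * np.pi, len(radar.columns), endpoint=False).tolist()
    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(polar=True)
    for mid in radar.index:
        vals = radar.loc[mid].tolist()
        ax.plot(angles + angles[:1], vals + vals[:1], label=f"{mid} {names[mid]}")
        ax.fill(angles + angles[:1], vals + vals[:1], alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels(radar.columns, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=7)
    ax.set_title("Normalised metrics, top-4 models")
    fig.savefig(figdir / "radar_top4.png", dpi=120)

    sel = frame.loc[comparison.selected]
    print(f"top-4 by R²: {', '.join(f'{m} ({names[m]})' for m in comparison.top4)}")
    print(
        f"selected: {comparison.selected} ({names[comparison.selected]}) — "
        f"MAE {sel.mae:.2f} g, MAPE {sel.mape:.2f}%, RMSE {sel.rmse:.2f} g, R² {sel.r2:.3f}"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
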