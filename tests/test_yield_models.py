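"""Registry structure, metric formulas, normalisation and model selection."""

import numpy as np
import pandas as pd
import pytest

from canopyield.registry import build_estimator, model_registry
from canopyield.types import MetricReport, ModelSpec
from canopyield.yield_models import (
    FittedModel,
    evaluate_model,
    fit_allometry,
    fit_model,
    normalize_metrics,
    rank_models,
    records_from_arrays,
    split_holdout,
)


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def fake_report(model_id, **overrides):
    base = dict(
        model_id=model_id, mae=10.0, mape=5.0, mse=100.0, rmse=10.0, r2=0.9,
        prediction_speed=1e4, training_time=0.5, model_size=5000,
    )
    base.update(overrides)
    return MetricReport(**base)


class TestRegistry:
    def test_twenty_eight_unique_ids(self):
        specs = model_registry()
        ids = [s.model_id for s in specs]
        assert len(specs) == 28
        assert len(set(ids)) == 28
        assert ids == [f"2.{i}" for i in range(1, 29)]

    def test_family_counts(self):
        counts = pd.Series([s.family for s in model_registry()]).value_counts()
        assert counts.to_dict() == {
            "linear": 4, "tree": 3, "svm": 6, "efficient_linear": 2,
            "ensemble": 2, "gpr": 4, "neural_network": 5, "kernel": 2,
        }

    def test_known_variant_names(self):
        by_id = {s.model_id: s for s in model_registry()}
        assert by_id["2.24"].variant_name == "Wide Neural Network"
        assert by_id["2.7"].variant_name == "Coarse Tree"
        assert by_id["2.20"].variant_name == "Exponential GPR"
        assert by_id["2.28"].variant_name == "Least Squares Kernel Regression"

    def test_interpretability_labels(self):
        easy = {s.model_id for s in model_registry() if s.interpretability == "easy"}
        assert easy == {"2.1", "2.2", "2.3", "2.4", "2.5", "2.6", "2.7", "2.8", "2.14", "2.15"}

    def test_every_spec_builds_an_estimator(self):
        for spec in model_registry():
            assert hasattr(build_estimator(spec), "fit")


class TestSplitHoldout:
    def test_sixty_records_quarter_split(self):
        records = records_from_arrays(np.arange(60.0), np.arange(60.0) + 100)
        train, val = split_holdout(records, 0.25, seed=0)
        assert len(train) == 45 and len(val) == 15

    def test_deterministic_partition(self):
        records = records_from_arrays(np.arange(20.0), np.arange(20.0) + 100)
        a = split_holdout(records, 0.25, seed=5)
        b = split_holdout(records, 0.25, seed=5)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_partition_property(self):
        records = records_from_arrays(np.arange(17.0), np.arange(17.0) + 100)
        train, val = split_holdout(records, 0.3, seed=2)
        combined = sorted(train.area_cm2.tolist() + val.area_cm2.tolist())
        assert combined == sorted(records.area_cm2.tolist())
        assert not set(train.area_cm2) & set(val.area_cm2)

    def test_too_few_records_rejected(self):
        records = records_from_arrays(np.arange(5.0), np.arange(5.0) + 1)
        with pytest.raises(ValueError):
            split_holdout(records, 0.25, seed=0)


class TestFitModel:
    def test_linear_model_recovers_exact_coefficients(self):
        areas = np.linspace(50, 200, 20)
        records = records_from_arrays(areas, 2 * areas + 5)
        spec = model_registry()[0]  # plain linear
        fitted = fit_model(spec, records)
        est = fitted.estimator
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-6)
        assert est.intercept_ == pytest.approx(5.0, abs=1e-6)
        report = evaluate_model(fitted, records)
        assert report.r2 == pytest.approx(1.0, abs=1e-9)

    def test_coarse_tree_degenerates_to_mean_predictor(self):
        areas = np.linspace(50, 200, 20)  # < 36 samples -> single leaf
        weights = 2 * areas + 5
        spec = next(s for s in model_registry() if s.model_id == "2.7")
        fitted = fit_model(spec, records_from_arrays(areas, weights))
        assert np.allclose(fitted.predict([60.0, 150.0]), weights.mean())

    def test_squared_exponential_gpr_interpolates_noiseless_data(self):
        areas = np.linspace(60, 200, 25)
        weights = 0.9 * areas**1.15
        spec = next(s for s in model_registry() if s.model_id == "2.18")
        fitted = fit_model(spec, records_from_arrays(areas, weights))
        assert np.abs(fitted.predict(areas) - weights).max() < 1e-3

    def test_training_metadata_recorded(self):
        records = records_from_arrays(np.linspace(1, 10, 10), np.linspace(2, 20, 10))
        fitted = fit_model(model_registry()[0], records)
        assert fitted.training_time >= 0
        assert fitted.model_size > 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_model(model_registry()[0], records_from_arrays([], []))


class TestEvaluateModel:
    def test_hand_computed_metrics(self):
        val = records_from_arrays([1.0, 2.0, 3.0], [100.0, 200.0, 300.0])

        class _Fixed:
            def predict(self, X):
                return np.array([110.0, 190.0, 330.0])

        model = FittedModel(model_registry()[0], _Fixed(), 0.0, 1)
        report = evaluate_model(model, val)
        assert report.mae == pytest.approx(16.667, abs=1e-3)
        assert report.mape == pytest.approx(8.333, abs=1e-3)
        assert report.mse == pytest.approx(366.667, abs=1e-3)
        assert report.rmse == pytest.approx(19.148, abs=1e-3)
        assert report.r2 == pytest.approx(0.945, abs=1e-3)

    def test_perfect_predictions(self):
        val = records_from_arrays([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])

        class _Echo:
            def predict(self, X):
                return np.asarray(X).ravel() * 10

        report = evaluate_model(FittedModel(model_registry()[0], _Echo(), 0.0, 1), val)
        assert report.mae == 0 and report.mse == 0 and report.r2 == 1

    def test_mean_predictor_gets_zero_r2(self):
        val = records_from_arrays([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        report = evaluate_model(FittedModel(model_registry()[0], _Const(20.0), 0.0, 1), val)
        assert report.r2 == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_weights_rejected(self):
        val = records_from_arrays([1.0, 2.0, 3.0], [10.0, 0.0, 30.0])
        with pytest.raises(ValueError, match="MAPE"):
            evaluate_model(FittedModel(model_registry()[0], _Const(1.0), 0.0, 1), val)

    def test_metrics_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(60, 200, 12)
        val = records_from_arrays(areas, 0.9 * areas**1.15)
        model = FittedModel(model_registry()[0], _Const(150.0), 0.0, 1)
        a = evaluate_model(model, val)
        b = evaluate_model(model, val.sample(frac=1.0, random_state=0))
        for name in ("mae", "mape", "mse", "rmse", "r2"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)


class TestNormalization:
    def test_direct_and_inverted_columns(self):
        reports = [
            fake_report("a", r2=2.0, mae=2.0),
            fake_report("b", r2=4.0, mae=4.0),
            fake_report("c", r2=6.0, mae=6.0),
        ]
        norm = normalize_metrics(reports)
        assert norm["r2"].tolist() == [0.0, 0.5, 1.0]  # higher better
        assert norm["mae"].tolist() == [1.0, 0.5, 0.0]  # lower better

    def test_constant_column_maps_to_zero(self):
        norm = normalize_metrics([fake_report("a"), fake_report("b")])
        assert (norm["mape"] == 0).all()

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            normalize_metrics([fake_report("a")])

    def test_values_bounded(self, noisy_comparison):
        assert (noisy_comparison.normalized.to_numpy() >= 0).all()
        assert (noisy_comparison.normalized.to_numpy() <= 1).all()


class TestRanking:
    def test_dominant_model_selected(self):
        reports = [fake_report(f"m{i}") for i in range(4)]
        reports.append(
            fake_report(
                "best", mae=1.0, mape=1.0, mse=1.0, rmse=1.0, r2=0.99,
                prediction_speed=1e6, training_time=0.01, model_size=10,
            )
        )
        result = rank_models(reports)
        assert result.selected == "best"
        assert result.composite_scores["best"] == pytest.approx(1.0)

    def test_top4_ordered_by_descending_r2(self):
        reports = [fake_report(f"m{i}", r2=0.5 + 0.1 * i) for i in range(4)]
        result = rank_models(reports)
        assert result.top4 == ["m3", "m2", "m1", "m0"]

    def test_r2_tie_broken_by_lower_rmse(self):
        reports = [
            fake_report("loose", r2=0.9, rmse=20.0),
            fake_report("tight", r2=0.9, rmse=10.0),
            fake_report("m3", r2=0.8),
            fake_report("m4", r2=0.7),
            fake_report("m5", r2=0.6),
        ]
        assert rank_models(reports).top4[0] == "tight"

    def test_too_few_reports_rejected(self):
        with pytest.raises(ValueError):
            rank_models([fake_report("a"), fake_report("b"), fake_report("c")])


class TestFixtureComparison:
    def test_full_registry_produces_28_reports(self, noisy_comparison):
        assert len(noisy_comparison.reports) == 28
        assert noisy_comparison.selected in noisy_comparison.top4

    def test_rmse_squares_to_mse(self, noisy_comparison):
        for report in noisy_comparison.reports:
            assert report.rmse**2 == pytest.approx(report.mse, rel=1e-9)

    def test_some_model_near_perfect_on_noiseless_data(self, noiseless_records):
        from canopyield.yield_models import compare_models

        comparison = compare_models(noiseless_records, seed=1)
        assert max(r.r2 for r in comparison.reports) >= 0.999


class TestAllometryFit:
    def test_exact_recovery_on_noiseless_data(self):
        areas = np.linspace(60, 200, 30)
        c, b = fit_allometry(areas, 0.9 * areas**1.15)
        assert c == pytest.approx(0.9, rel=1e-9)
        assert b == pytest.approx(1.15, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_allometry([1.0, -2.0], [1.0, 2.0])
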