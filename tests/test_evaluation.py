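"""Metrics, cross-validation mechanics, and grid selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ssenet import (
    ConfusionCounts,
    DesignData,
    FitControl,
    PriorSpec,
    auc_score,
    binomial_deviance,
    classify,
    confusion_metrics,
    grid_select,
    kfold_cv,
    prediction_error_metrics,
    stratified_folds,
)
from ssenet.evaluation import _choose_best

from .helpers import auc_brute_force


class TestBinomialDeviance:
    @pytest.mark.parametrize(
        "y, p, expected",
        [([0, 1, 0, 1], [0.5] * 4, 8 * np.log(2)),
         ([1, 0], [0.8, 0.3], -2 * (np.log(0.8) + np.log(0.7)))],
    )
    def test_closed_values(self, y, p, expected):
        assert binomial_deviance(np.array(y, float), np.array(p)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_perfect_fit_is_numerically_zero(self):
        y = np.array([0.0, 1.0, 1.0])
        assert binomial_deviance(y, y) < 1e-7

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binomial_deviance(np.zeros(3), np.full(2, 0.5))


class TestPredictionErrorMetrics:
    def test_uninformative_predictions_balanced_outcome(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = prediction_error_metrics(y, np.full(4, 0.5))
        assert m["mse"] == pytest.approx(0.25)
        assert m["mae"] == pytest.approx(0.5)
        assert m["mc"] == 0.0  # strict inequality: 0.5 never misclassifies

    def test_auc_derived_pair_count(self):
        y = np.array([0, 0, 1, 1.0])
        p = np.array([0.1, 0.4, 0.35, 0.8])
        assert prediction_error_metrics(y, p)["auc"] == pytest.approx(0.75)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1.0])
        m = prediction_error_metrics(y, y)
        assert m["mse"] == m["mae"] == m["mc"] == 0.0 and m["auc"] == 1.0

    def test_single_class_auc_is_missing(self):
        assert np.isnan(prediction_error_metrics(np.ones(3), np.full(3, 0.6))["auc"])

    def test_auc_matches_brute_force_and_sklearn(self, rng):
        for _ in range(30):
            n = rng.integers(5, 40)
            y = np.zeros(n)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.uniform(size=n), 2)  # coarse grid to force ties
            ours = auc_score(y, p)
            assert ours == pytest.approx(auc_brute_force(y, p), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestClassify:
    def test_strict_boundary(self):
        np.testing.assert_array_equal(
            classify(np.array([0.49, 0.5, 0.51])), [0, 0, 1]
        )

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2])
    def test_invalid_threshold_rejected(self, threshold):
        with pytest.raises(ValueError):
            classify(np.array([0.7]), threshold)

    def test_constant_high_probabilities(self):
        assert classify(np.full(4, 0.7)).tolist() == [1, 1, 1, 1]


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(m[k] == 1.0 for k in m)

    def test_chance_symmetry(self):
        m = confusion_metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert m["mcc"] == pytest.approx(0.0)
        assert m["f1"] == pytest.approx(0.5)
        assert m["ac"] == pytest.approx(0.5)

    def test_unbalanced_derived_values(self):
        m = confusion_metrics(ConfusionCounts(tp=30, fn=9, tn=230, fp=4))
        assert m["sn"] == pytest.approx(0.76923, abs=1e-5)
        assert m["sp"] == pytest.approx(0.98291, abs=1e-5)
        assert m["ppv"] == pytest.approx(0.88235, abs=1e-5)
        assert m["npv"] == pytest.approx(0.96234, abs=1e-5)
        # 6864 / sqrt(1326 * 55926) evaluated directly
        assert m["mcc"] == pytest.approx(0.797074, abs=1e-5)
        assert m["f1"] == pytest.approx(0.82192, abs=1e-5)

    def test_zero_denominators_are_missing(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert np.isnan(m["ppv"]) and np.isnan(m["mcc"])
        assert m["sp"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_mcc_invariances_on_random_tables(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            m = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            swapped = confusion_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            inverted = confusion_metrics(ConfusionCounts(tp=fn, fp=tn, tn=fp, fn=tp))
            assert m["mcc"] == pytest.approx(swapped["mcc"], abs=1e-12)
            assert m["mcc"] == pytest.approx(-inverted["mcc"], abs=1e-12)


class TestStratifiedFolds:
    def test_partition_each_subject_once(self):
        y = np.array([0, 1] * 5)
        folds = stratified_folds(y, 5, seed=0)
        held = np.concatenate([te for _, te in folds])
        assert sorted(held.tolist()) == list(range(10))
        assert all(len(te) == 2 for _, te in folds)

    def test_stratification_preserves_minority_class(self):
        y = np.array([0] * 8 + [1] * 2)
        for _, te in stratified_folds(y, 2, seed=3):
            assert y[te].sum() == 1

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            stratified_folds(np.array([0] * 9 + [1]), 5, seed=0)


def _constant_predictor_data():
    X = np.ones((10, 3))
    y = np.array([1, 0, 0, 0, 0, 1, 0, 0, 0, 0])
    return DesignData.from_arrays(X, y)


class TestKFoldCV:
    def test_constant_predictors_give_training_base_rate_deviance(self):
        """With no usable predictors each held-out prediction is the training
        fold's event rate; CV deviance matches the hand-computed null value."""
        data = _constant_predictor_data()
        prior = PriorSpec.from_model_name("lasso", 1.0)
        res = kfold_cv(data, prior, k=2, seed=0, control=FitControl(cd_tol=1e-10))
        folds = stratified_folds(data.y.astype(int), 2, seed=0)
        expected = np.empty(10)
        for tr, te in folds:
            expected[te] = data.y[tr].mean()
        np.testing.assert_allclose(res.predictions[0], expected, atol=1e-6)
        manual = binomial_deviance(data.y, expected)
        assert res.metrics["deviance"] == pytest.approx(manual, abs=1e-4)

    def test_each_subject_predicted_once_per_repeat(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        prior = PriorSpec.from_model_name("lasso", 0.05)
        res = kfold_cv(data, prior, k=5, repeats=2, seed=1)
        assert res.predictions.shape == (2, data.n_subjects)
        assert np.isfinite(res.predictions).all()
        assert (res.fold_ids >= 0).all()

    def test_pooled_metrics_match_confusion_path(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        prior = PriorSpec.from_model_name("en", 0.05)
        res = kfold_cv(data, prior, k=5, seed=2)
        preds = res.predictions[0]
        counts = ConfusionCounts.from_labels(data.y, classify(preds))
        recomputed = confusion_metrics(counts)
        for key, val in recomputed.items():
            assert res.metrics[key] == pytest.approx(val, nan_ok=True)

    def test_repeated_cv_reproducible(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        prior = PriorSpec.from_model_name("ssl", 0.1, 1.0)
        r1 = kfold_cv(data, prior, k=5, repeats=2, seed=9)
        r2 = kfold_cv(data, prior, k=5, repeats=2, seed=9)
        assert np.array_equal(r1.predictions, r2.predictions)
        assert r1.metrics == r2.metrics


class TestGridSelect:
    def test_chosen_point_attains_minimal_deviance(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        template = PriorSpec.from_model_name("ssen", 0.05, 1.0)
        report = grid_select(
            data, template, s0_grid=(0.05, 0.2), s1_grid=(1.0, 2.0), k=5, seed=4
        )
        assert report.chosen_row["deviance"] == report.records["deviance"].min()
        assert len(report.records) == 4

    def test_inadmissible_pairs_skipped(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        template = PriorSpec.from_model_name("ssl", 0.05, 1.0)
        report = grid_select(
            data, template, s0_grid=(0.05, 1.5), s1_grid=(1.0,), k=5, seed=4
        )
        assert report.records[["s0", "s1"]].values.tolist() == [[0.05, 1.0]]

    def test_empty_admissible_grid_rejected(self, tiny_dataset):
        data = DesignData.from_arrays(tiny_dataset.X, tiny_dataset.y)
        template = PriorSpec.from_model_name("ssl", 0.05, 1.0)
        with pytest.raises(ValueError, match="admissible"):
            grid_select(data, template, s0_grid=(2.0,), s1_grid=(1.0,))

    def test_deviance_ties_broken_by_smaller_scales(self):
        records = pd.DataFrame(
            {"s0": [0.2, 0.1, 0.1], "s1": [1.0, 2.0, 1.0],
             "deviance": [5.0, 5.0, 5.0]}
        )
        assert _choose_best(records) == (0.1, 1.0)

    def test_strictly_smallest_point_chosen(self):
        records = pd.DataFrame(
            {"s0": [0.1, 0.2], "s1": [1.0, 1.0], "deviance": [9.0, 3.0]}
        )
        assert _choose_best(records) == (0.2, 1.0)
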