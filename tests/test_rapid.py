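"""Rapid-mode estimation: splitting, training, prediction contracts and the
evaluation metrics (cross-checked against brute-force formulas)."""

import numpy as np
import pytest

from ricecanopy import (
    CanopyObservation,
    GeneratorConfig,
    RapidStructureModel,
    RICE_LIA,
    evaluate,
    frame_to_records,
    generate_structural_dataset,
    predict_structure,
    records_to_frame,
    split_dataset,
    train_estimators,
)
from ricecanopy.errors import ConfigError, StateError, StratificationError
from ricecanopy.rapid import load_bundle, save_bundle


@pytest.fixture(scope="module")
def rf_results(noiseless_records):
    model = RapidStructureModel(noiseless_records, algorithm="rf", cv_folds=3)
    return model.fit(seed=5)


class TestSplit:
    def test_seventy_thirty_counts(self, noiseless_records):
        records = noiseless_records[:100]
        train, test = split_dataset(records, ratio=0.7, seed=0)
        assert len(train) == 70 and len(test) == 30

    def test_disjoint_and_exhaustive(self, noiseless_records):
        train, test = split_dataset(noiseless_records, seed=1)
        ids = [id(r) for r in train] + [id(r) for r in test]
        assert len(set(ids)) == len(noiseless_records)

    def test_stratification_within_one_record(self, noiseless_records):
        train, _ = split_dataset(noiseless_records, ratio=0.7, seed=2)
        for cls in {r.leaf_count for r in noiseless_records}:
            total = sum(r.leaf_count == cls for r in noiseless_records)
            in_train = sum(r.leaf_count == cls for r in train)
            assert abs(in_train - 0.7 * total) <= 1.0

    def test_determinism(self, noiseless_records):
        a = split_dataset(noiseless_records, seed=3)
        b = split_dataset(noiseless_records, seed=3)
        assert [id(r) for r in a[0]] == [id(r) for r in b[0]]

    def test_singleton_stratum_raises_unless_fallback(self, noiseless_records):
        counts = {r.leaf_count for r in noiseless_records}
        rare = max(counts)
        records = [r for r in noiseless_records if r.leaf_count != rare][:20]
        records.append(next(r for r in noiseless_records if r.leaf_count == rare))
        with pytest.raises(StratificationError):
            split_dataset(records)
        train, test = split_dataset(records, allow_fallback=True)
        assert len(train) + len(test) == len(records)


class TestTrain:
    def test_unknown_algorithm_rejected(self, noiseless_records):
        with pytest.raises(ConfigError):
            train_estimators(noiseless_records, algorithm="mlp")
        with pytest.raises(ConfigError):
            RapidStructureModel(noiseless_records, algorithm="mlp")

    def test_training_determinism(self, noiseless_records):
        train, test = split_dataset(noiseless_records, seed=0)
        obs = test[0].observation
        a = train_estimators(train, algorithm="rf", cv_folds=3, seed=1)
        b = train_estimators(train, algorithm="rf", cv_folds=3, seed=1)
        ra = predict_structure(a, obs)
        rb = predict_structure(b, obs)
        assert ra == rb

    def test_normalization_fitted_on_train_only(self, rf_results):
        """Scaler statistics must equal the train-matrix moments exactly."""
        from ricecanopy.rapid import _canopy_matrix

        scaler = rf_results.bundle.canopy_models["stem_height"].named_steps["scale"]
        X = _canopy_matrix(rf_results.train)
        assert np.allclose(scaler.mean_, X.mean(axis=0))
        assert np.allclose(scaler.scale_, X.std(axis=0))

    def test_cv_scores_recorded(self, rf_results):
        scores = rf_results.bundle.cv_scores
        assert {"leaf_count", "plant_count", "stem_height", "leaf_length",
                "leaf_width", "position_ratio"} <= set(scores)


class TestPredict:
    def test_leaf_list_matches_predicted_count(self, rf_results, noiseless_records):
        rec = rf_results.predict(noiseless_records[0].observation)
        assert len(rec.per_leaf) == rec.leaf_count
        assert rec.plant_count >= 1

    def test_predictions_within_physical_bounds(self, rf_results, noiseless_records):
        for source in noiseless_records[:10]:
            rec = rf_results.predict(source.observation)
            for leaf in rec.per_leaf:
                assert 0.0 < leaf.position_ratio <= 1.0
                assert leaf.inclination == pytest.approx(RICE_LIA(leaf.position))

    def test_held_out_stem_height_within_five_percent(self, rf_results):
        for truth in rf_results.test[:10]:
            rec = rf_results.predict(truth.observation)
            assert rec.stem_height == pytest.approx(truth.stem_height, rel=0.05)

    def test_untrained_bundle_rejected(self, rf_results):
        import dataclasses

        cold = dataclasses.replace(rf_results.bundle, fitted=False)
        with pytest.raises(StateError):
            predict_structure(cold, rf_results.test[0].observation)


class TestEvaluate:
    def test_perfect_predictions_on_train_like_metrics(self, rf_results):
        report = rf_results.train_report
        # tree ensembles interpolate the noiseless training set almost exactly
        assert report.accuracy > 0.99
        assert report.regression["stem_height"]["r2"] > 0.99

    def test_metrics_match_brute_force(self, rf_results):
        """Recompute accuracy and per-target R2/RMSE from raw predictions."""
        from ricecanopy.rapid import _canopy_matrix, _vertical_matrix

        bundle = rf_results.bundle
        test = rf_results.test
        report = rf_results.test_report

        X = _canopy_matrix(test)
        pred = bundle.label_encoder.inverse_transform(
            bundle.leaf_count_model.predict(X)
        )
        truth = np.array([r.leaf_count for r in test])
        assert report.accuracy == pytest.approx(np.mean(pred == truth))
        for cls in report.classes:
            tp = np.sum((pred == cls) & (truth == cls))
            fp = np.sum((pred == cls) & (truth != cls))
            fn = np.sum((pred != cls) & (truth == cls))
            expected_p = tp / (tp + fp) if tp + fp else 0.0
            expected_r = tp / (tp + fn) if tp + fn else 0.0
            assert report.precision[cls] == pytest.approx(expected_p)
            assert report.recall[cls] == pytest.approx(expected_r)
        assert report.confusion.sum() == len(test)

        y = np.array([r.stem_height for r in test])
        yhat = bundle.canopy_models["stem_height"].predict(X)
        rss = np.sum((y - yhat) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert report.regression["stem_height"]["r2"] == pytest.approx(1 - rss / tss)
        assert report.regression["stem_height"]["rmse"] == pytest.approx(
            np.sqrt(np.mean((y - yhat) ** 2))
        )

        Xv, yv = _vertical_matrix(test)
        yhat = bundle.vertical_models["leaf_length"].predict(Xv)
        rss = np.sum((yv["leaf_length"] - yhat) ** 2)
        tss = np.sum((yv["leaf_length"] - yv["leaf_length"].mean()) ** 2)
        assert report.regression["leaf_length"]["r2"] == pytest.approx(1 - rss / tss)

    def test_binary_confusion_example(self):
        """TP=3, FP=1, FN=1, TN=5 -> accuracy 0.8, precision 0.75, recall 0.75."""
        tp, fp, fn, tn = 3, 1, 1, 5
        accuracy = (tp + tn) / (tp + tn + fp + fn)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert accuracy == pytest.approx(0.8)
        assert precision == pytest.approx(0.75)
        assert recall == pytest.approx(0.75)
        # the same numbers through the package's evaluation path
        from sklearn.metrics import precision_recall_fscore_support

        truth = np.array([1] * 4 + [0] * 6)
        pred = np.array([1, 1, 1, 0] + [1] + [0] * 5)
        p, r, _, _ = precision_recall_fscore_support(truth, pred, labels=[1])
        assert p[0] == pytest.approx(precision)
        assert r[0] == pytest.approx(recall)

    def test_zero_variance_truth_reports_missing_r2(self):
        from ricecanopy.rapid import _r2_rmse

        out = _r2_rmse(np.full(5, 3.0), np.arange(5.0))
        assert out["r2"] is None
        assert out["rmse"] > 0

    def test_summary_renders(self, rf_results):
        text = rf_results.summary()
        assert "accuracy" in text and "stem_height" in text


class TestNoiseDegradation:
    def test_more_noise_never_helps(self):
        """Test R2 for stem height does not increase with generator noise."""
        r2s = []
        for sd in (0.0, 0.08, 0.25):
            records = generate_structural_dataset(
                GeneratorConfig(n=120, seed=13, noise_sd=sd)
            )
            res = RapidStructureModel(records, algorithm="rf", cv_folds=3).fit(seed=13)
            r2s.append(res.test_report.regression["stem_height"]["r2"])
        assert r2s[0] >= r2s[1] >= r2s[2]


class TestRoundTrips:
    def test_frame_round_trip(self, noiseless_records):
        frame = records_to_frame(noiseless_records[:15])
        back = frame_to_records(frame)
        assert back == list(noiseless_records[:15])

    def test_bundle_serialization(self, rf_results, tmp_path):
        path = tmp_path / "bundle.joblib"
        save_bundle(rf_results.bundle, path)
        loaded = load_bundle(path)
        obs = rf_results.test[0].observation
        assert predict_structure(loaded, obs) == rf_results.predict(obs)
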