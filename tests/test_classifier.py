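"""Class balancing, network training and prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neural_network import MLPClassifier

from mobiward import LabeledDataset, ValidationError, balance_classes, predict, train
from mobiward.classifier import AnnModel
from mobiward.synthetic import generate_calibration_session


def _dataset(counts, n_features=5, seed=0, separation=6.0):
    """Six Gaussian blobs with the given per-class counts."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, n in zip(range(1, 7), counts):
        center = rng.normal(scale=separation, size=n_features)
        X.append(center + rng.normal(size=(n, n_features)))
        y.extend([c] * n)
    return LabeledDataset(
        np.vstack(X), np.array(y), np.arange(len(y)), [f"f{i}" for i in range(n_features)]
    )


class TestBalanceClasses:
    def test_equal_counts_unchanged(self):
        ds = _dataset([20] * 6)
        out = balance_classes(ds, seed=0)
        assert out.class_counts() == {c: 20 for c in range(1, 7)}

    def test_downsampled_to_minimum(self):
        """(60,50,40,30,25,10) -> every class at 10, total 60."""
        ds = _dataset([60, 50, 40, 30, 25, 10])
        out = balance_classes(ds, seed=0)
        assert out.class_counts() == {c: 10 for c in range(1, 7)}
        assert out.n_samples == 60

    def test_absent_class_named_in_error(self):
        ds = _dataset([20, 20, 20, 20, 20, 20])
        sub = ds.subset(ds.labels != 5)
        with pytest.raises(ValidationError, match="cycling"):
            balance_classes(sub, seed=0)

    def test_static_dynamic_ratio_option(self):
        """With ratio 3, static classes are capped at 3x the smallest dynamic."""
        ds = _dataset([90, 90, 90, 20, 25, 30])
        out = balance_classes(ds, seed=0, static_dynamic_ratio=3.0)
        counts = out.class_counts()
        assert counts[1] == counts[2] == counts[3] == 60
        assert counts[4] == 20 and counts[5] == 25 and counts[6] == 30

    def test_seeded_and_shuffled(self):
        ds = _dataset([60, 50, 40, 30, 25, 10])
        out1 = balance_classes(ds, seed=1)
        out2 = balance_classes(ds, seed=1)
        np.testing.assert_array_equal(out1.features, out2.features)
        # shuffled: not grouped by class
        assert not (np.diff(out1.labels) >= 0).all()


class TestTrain:
    def test_separable_blobs_high_training_accuracy(self):
        ds = _dataset([100] * 6, n_features=10)
        model = train(ds, seed=0)
        pred, _ = predict(model, ds.features)
        assert (pred == ds.labels).mean() >= 0.99

    def test_shuffled_labels_at_chance(self):
        """Destroying the labels leaves held-out accuracy near 1/6."""
        rng = np.random.default_rng(0)
        ds = _dataset([120] * 6, n_features=10)
        y = rng.permutation(ds.labels)
        train_idx, test_idx = np.arange(0, 600), np.arange(600, 720)
        model = train(
            LabeledDataset(ds.features[train_idx], y[train_idx], ds.subject_ids[train_idx]),
            seed=0,
        )
        pred, _ = predict(model, ds.features[test_idx])
        acc = (pred == y[test_idx]).mean()
        assert abs(acc - 1 / 6) <= 0.1

    def test_deterministic_given_seed(self):
        ds = _dataset([50] * 6)
        m1, m2 = train(ds, seed=4), train(ds, seed=4)
        for a, b in zip(m1.estimator.coefs_, m2.estimator.coefs_):
            np.testing.assert_array_equal(a, b)

    def test_architecture(self):
        ds = _dataset([30] * 6, n_features=7)
        model = train(ds, seed=0)
        assert model.hidden_weights.shape == (7, 18)
        assert model.output_weights.shape == (18, 6)
        assert model.estimator.activation == "tanh"
        assert model.n_epochs_run <= 500

    def test_too_few_samples_rejected(self):
        ds = _dataset([1, 5, 5, 5, 5, 5])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            train(ds)


class TestPredict:
    def test_probability_rows_sum_to_one(self, rng):
        ds = _dataset([40] * 6)
        model = train(ds, seed=0)
        _, proba = predict(model, rng.normal(size=(25, 5)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        ds = _dataset([40] * 6)
        model = train(ds, seed=0)
        with pytest.raises(ValidationError, match="dimension"):
            predict(model, rng.normal(size=(3, 4)))

    def test_hand_set_weights_realize_known_rule(self):
        """A manually wired network labels unit vectors by their hot axis."""
        base = _dataset([5] * 6, n_features=6)
        est = MLPClassifier(hidden_layer_sizes=(18,), activation="tanh", max_iter=5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(base.features, base.labels)
        w1 = np.zeros((6, 18))
        w1[:6, :6] = 0.1 * np.eye(6)  # feature j -> hidden node j (linear regime)
        w2 = np.zeros((18, 6))
        w2[:6, :6] = 50.0 * np.eye(6)  # hidden node j -> class code j+1
        est.coefs_ = [w1, w2]
        est.intercepts_ = [np.zeros(18), np.zeros(6)]
        model = AnnModel(estimator=est, input_dim=6, seed=0)
        X = np.eye(6)[[2, 0, 5]]  # hot axes 2, 0, 5
        labels, _ = predict(model, X)
        np.testing.assert_array_equal(labels, [3, 1, 6])

    def test_roundtrip_serialization(self, tmp_path):
        ds = _dataset([30] * 6)
        model = train(ds, seed=0)
        model.save(tmp_path / "model.pkl")
        back = AnnModel.load(tmp_path / "model.pkl")
        p1, _ = predict(model, ds.features[:10])
        p2, _ = predict(back, ds.features[:10])
        np.testing.assert_array_equal(p1, p2)


class TestClassifyStream:
    def test_lying_recording_labelled_lying(self, trained_pipeline):
        """A 60 s static lying recording is classified lying nearly throughout."""
        session = generate_calibration_session("SX", duration_s=60.0, seed=99)
        # lying is the third 60 s block of the protocol (stand, sit, lie, ...)
        start = 2 * 60 * 100
        sl = slice(start, start + 60 * 100)
        arm = session.arm
        leg = session.leg
        from mobiward import SensorTrace

        arm_ly = SensorTrace("arm", 100.0, arm.start_time, arm.samples[sl])
        leg_ly = SensorTrace("leg", 100.0, leg.start_time, leg.samples[sl])
        timeline = trained_pipeline.classify_stream(arm_ly, leg_ly, patient_id="SX")
        assert len(timeline) == 23  # floor(6000 / 256)
        frac_lying = np.mean([e.code == 1 for e in timeline.entries])
        assert frac_lying >= 0.90

    def test_entry_count_matches_windowing(self, trained_pipeline, rng):
        from mobiward import SensorTrace

        start = pd.Timestamp("2020-06-20 10:00:00")
        arm = SensorTrace("arm", 100.0, start, rng.normal(0, 0.02, (1024, 3)) + [0, 1, 0])
        leg = SensorTrace("leg", 100.0, start, rng.normal(0, 0.02, (1024, 3)) + [0, 1, 0])
        timeline = trained_pipeline.classify_stream(arm, leg)
        assert len(timeline) == 4  # 1024 samples / 256

    def test_single_site_rejected(self, trained_pipeline, rng):
        from mobiward import SensorTrace

        arm = SensorTrace(
            "arm", 100.0, pd.Timestamp("2020-06-20"), rng.normal(size=(512, 3))
        )
        with pytest.raises(ValidationError, match="ablation"):
            trained_pipeline.classify_stream(arm, None)
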