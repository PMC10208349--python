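"""RBF-SVM training, prediction and serialization."""

import math

import numpy as np
import pytest

from tidemark import synthetic
from tidemark.classify import (SVMConfig, TrainingSet, load_model,
                               predict_map, rbf_gram, rbf_kernel,
                               sample_training, save_model, train)
from tidemark.raster import CLASS_CODES, ClassRaster, apply_mask


def two_clouds(n=500, gap=3.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n, 3))
    b = rng.normal(gap * sd, sd, size=(n, 3))
    X = np.vstack([a, b])
    y = np.r_[np.full(n, 1), np.full(n, 2)]
    return TrainingSet(X, y, ("SWIR1", "NIR", "Red"), seed)


def separable_clouds(n=300, seed=0):
    """Disjoint uniform boxes with a unit gap per band: hard-margin regime."""
    rng = np.random.default_rng(seed)
    a = rng.random((n, 3))
    b = rng.random((n, 3)) + 2.0
    X = np.vstack([a, b])
    y = np.r_[np.full(n, 1), np.full(n, 2)]
    return TrainingSet(X, y, ("SWIR1", "NIR", "Red"), seed)


class TestKernel:
    def test_zero_distance_gives_one(self):
        assert rbf_kernel([1, 2, 3], [1, 2, 3], g=0.091) == 1.0

    def test_half_value_at_inverted_distance(self):
        # ||x - x'||^2 = ln(2)/g  =>  K = 0.5
        d2 = math.log(2) / 0.091
        x = np.zeros(3)
        y = np.array([math.sqrt(d2), 0, 0])
        assert rbf_kernel(x, y, g=0.091) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric(self):
        x, y = np.array([0.1, 0.4, 0.2]), np.array([0.3, 0.2, 0.5])
        assert rbf_kernel(x, y, 0.091) == rbf_kernel(y, x, 0.091)

    def test_gram_matrix_psd(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 3))
        K = rbf_gram(X, X, 0.091)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_nonpositive_g_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0], [1], g=0)


class TestSampling:
    def test_exhaustive_class_fully_selected(self, small_truth, calibration):
        truth = small_truth.class_maps[0]
        scene = synthetic.render_scene(truth, small_truth.signatures,
                                       calibration, 0.0, seed=2)
        n_mangrove = truth.class_counts()[1]
        ts = sample_training(truth, scene, ("SWIR1", "NIR", "Red"),
                             n_per_class=n_mangrove, seed=0)
        assert ts.class_counts()[1] == n_mangrove

    def test_deterministic_given_seed(self, small_truth, calibration):
        truth = small_truth.class_maps[0]
        scene = synthetic.render_scene(truth, small_truth.signatures,
                                       calibration, 1.0, seed=2)
        a = sample_training(truth, scene, ("SWIR1", "NIR"), 100, seed=9)
        b = sample_training(truth, scene, ("SWIR1", "NIR"), 100, seed=9)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)

    def test_exact_counts_per_class(self, small_truth, calibration):
        truth = small_truth.class_maps[0]
        scene = synthetic.render_scene(truth, small_truth.signatures,
                                       calibration, 1.0, seed=2)
        ts = sample_training(truth, scene, ("SWIR1", "NIR", "Red"), 400, seed=1)
        assert ts.class_counts() == {1: 400, 2: 400}

    def test_insufficient_pixels_raise(self, small_truth, calibration):
        truth = small_truth.class_maps[0]
        scene = synthetic.render_scene(truth, small_truth.signatures,
                                       calibration, 1.0, seed=2)
        with pytest.raises(ValueError, match="eligible"):
            sample_training(truth, scene, ("SWIR1",), 10**6, seed=1)


class TestTrain:
    def test_separable_clouds_perfect_training_accuracy(self):
        ts = separable_clouds()
        model = train(ts, SVMConfig())
        assert (model.predict(ts.features) == ts.labels).mean() == 1.0

    def test_duplicating_points_leaves_decision_unchanged(self):
        # hard-margin regime: duplicates split the dual weight, leaving the
        # decision surface untouched (up to solver tolerance)
        cfg = SVMConfig(tolerance=1e-8)
        ts = separable_clouds(n=150, seed=3)
        dup = TrainingSet(np.vstack([ts.features, ts.features]),
                          np.r_[ts.labels, ts.labels], ts.band_labels)
        probe = np.random.default_rng(4).random((64, 3)) * 3
        f1 = train(ts, cfg).decision_function(probe)
        f2 = train(dup, cfg).decision_function(probe)
        assert np.allclose(f1, f2, atol=1e-5)

    def test_label_swap_flips_decision_sign(self):
        cfg = SVMConfig(tolerance=1e-8)
        ts = separable_clouds(n=150, seed=5)
        swapped = TrainingSet(ts.features, np.where(ts.labels == 1, 2, 1),
                              ts.band_labels)
        probe = np.random.default_rng(6).random((32, 3)) * 3
        f = train(ts, cfg).decision_function(probe)
        g = train(swapped, cfg).decision_function(probe)
        assert np.allclose(f, -g, atol=1e-5)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError):
            train(TrainingSet(X, np.ones(10, dtype=int), ("a", "b", "c")))


class TestPredictMap:
    def test_zero_noise_scene_recovered_exactly(self, small_truth,
                                                calibration,
                                                zero_noise_scene):
        truth = small_truth.class_maps[0]
        ts = sample_training(truth, zero_noise_scene, ("SWIR1", "NIR", "Red"),
                             400, seed=0)
        model = train(ts, SVMConfig())
        pred = predict_map(model, zero_noise_scene)
        assert np.array_equal(pred.codes, truth.codes)

    def test_all_masked_scene_gives_all_nodata(self, small_truth,
                                               calibration, zero_noise_scene):
        truth = small_truth.class_maps[0]
        ts = sample_training(truth, zero_noise_scene, ("SWIR1", "NIR", "Red"),
                             400, seed=0)
        model = train(ts, SVMConfig())
        full = np.ones(truth.geometry.shape, dtype=bool)
        masked = type(zero_noise_scene)(
            {lab: apply_mask(b, full) for lab, b in zero_noise_scene.bands.items()},
            epoch=zero_noise_scene.epoch)
        assert (predict_map(model, masked).codes == 0).all()

    def test_prediction_deterministic(self, small_truth, zero_noise_scene):
        truth = small_truth.class_maps[0]
        ts = sample_training(truth, zero_noise_scene, ("SWIR1", "NIR", "Red"),
                             400, seed=0)
        model = train(ts, SVMConfig())
        a = predict_map(model, zero_noise_scene)
        b = predict_map(model, zero_noise_scene)
        assert np.array_equal(a.codes, b.codes)

    def test_missing_band_raises(self, small_truth, zero_noise_scene):
        truth = small_truth.class_maps[0]
        ts = sample_training(truth, zero_noise_scene, ("SWIR1", "NIR"), 400,
                             seed=0)
        model = train(ts, SVMConfig())
        with pytest.raises(Exception, match="lacks"):
            predict_map(model, zero_noise_scene, band_labels=("SWIR1", "Pan"))


class TestAccuracyVsNoise:
    def test_accuracy_monotone_non_increasing_in_noise(self, small_truth,
                                                       calibration):
        truth = small_truth.class_maps[0]
        accs = []
        for sigma in (0.0, 0.01, 0.05, 0.1):
            sig = synthetic.default_signatures(sd=sigma) if sigma else \
                synthetic.default_signatures(sd=0.0)
            scene = synthetic.render_scene(truth, sig, calibration, 1.0,
                                           seed=21)
            ts = sample_training(truth, scene, ("SWIR1", "NIR", "Red"), 400,
                                 seed=1)
            model = train(ts, SVMConfig())
            pred = predict_map(model, scene)
            accs.append((pred.codes == truth.codes).mean())
        assert all(a >= b - 1e-12 for a, b in zip(accs, accs[1:])), accs
        assert accs[0] == 1.0


class TestSerialization:
    def test_saved_model_reproduces_decision_bitwise(self, tmp_path):
        ts = two_clouds(n=200, seed=8)
        model = train(ts, SVMConfig())
        loaded = load_model(save_model(model, tmp_path / "m.npz"))
        probe = np.random.default_rng(9).random((128, 3)) * 3
        assert np.array_equal(model.decision_function(probe),
                              loaded.decision_function(probe))
        assert loaded.band_labels == model.band_labels
        assert loaded.class_counts == model.class_counts

    def test_decision_matches_sklearn_reference(self):
        # the stored dual form must reproduce sklearn's own decision values
        from sklearn.svm import SVC
        ts = two_clouds(n=200, seed=10)
        model = train(ts, SVMConfig())
        svc = SVC(kernel="rbf", gamma=0.091, C=100.0, tol=1e-3)
        svc.fit(ts.features, ts.labels)
        probe = np.random.default_rng(11).random((64, 3)) * 3
        assert np.allclose(model.decision_function(probe),
                           svc.decision_function(probe), atol=1e-10)
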