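"""Network construction, training behavior and the shared classifier contract."""

import numpy as np
import pytest
from scipy.signal import correlate

from hsibrain import (
    HybridArchSpec,
    TrainConfig,
    build_1d_dnn,
    build_2d_cnn,
    build_hybrid_cnn,
    extract_features,
    train_svm,
)
from hsibrain.errors import ArchitectureError, StateError, ValidationError
from hsibrain.nn import Conv2D, Conv3D, Dense, Flatten, MergeSpectral
from tests.conftest import make_separable_patches

SMALL = HybridArchSpec.small(12, patch_size=11)
CFG = TrainConfig(epochs=30, batch_size=32, seed=0)


class TestArchitectures:
    def test_hybrid_layer_sequence(self):
        clf = build_hybrid_cnn(HybridArchSpec())
        kinds = [type(l).__name__ for l in clf.network.layers if l.params or
                 isinstance(l, (MergeSpectral, Flatten))]
        assert kinds == (["Conv3D"] * 4 + ["MergeSpectral"] + ["Conv2D"] * 2
                         + ["Flatten"] + ["Dense"] * 3)

    def test_hybrid_output_is_four_classes(self):
        clf = build_hybrid_cnn(HybridArchSpec())
        assert clf.network.layers[-1].W.shape[1] == 4

    def test_hybrid_forward_gives_probabilities(self, rng):
        clf = build_hybrid_cnn(SMALL)
        clf.trained = True  # inference-only check on an untrained stack
        probs = clf.predict_proba(np.zeros((3, 11, 11, 12)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (3, 4)

    def test_hybrid_spec_shape_invariants(self):
        with pytest.raises(ValidationError):
            HybridArchSpec(conv3d_layers=((4, (3, 3, 3)),) * 3)
        with pytest.raises(ValidationError):
            HybridArchSpec(dense_layers=(64, 32, 3))

    def test_oversized_kernel_reports_layer_index(self):
        spec = HybridArchSpec(
            input_shape=(11, 11, 8),
            conv3d_layers=((4, (3, 3, 7)), (4, (3, 3, 5)), (4, (3, 3, 3)), (4, (3, 3, 3))),
            conv2d_layers=((8, (3, 3)), (8, (3, 3))),
            dense_layers=(16, 8, 4),
        )
        with pytest.raises(ArchitectureError, match="layer 1"):
            build_hybrid_cnn(spec)

    def test_2d_cnn_topology(self):
        clf = build_2d_cnn((11, 11, 12))
        names = [type(l).__name__ for l in clf.network.layers]
        assert names.count("Conv2D") == 3
        assert names.count("AvgPool2D") == 1
        assert names.count("Dense") == 3

    def test_2d_cnn_smaller_than_hybrid_on_same_input(self):
        hybrid = build_hybrid_cnn(HybridArchSpec())
        flat2d = build_2d_cnn((11, 11, 100))
        assert flat2d.parameter_count() < hybrid.parameter_count()

    def test_1d_dnn_hidden_widths(self):
        clf = build_1d_dnn(24)
        dense = [l for l in clf.network.layers if isinstance(l, Dense)]
        assert [d.W.shape for d in dense] == [(24, 28), (28, 40), (40, 4)]

    def test_1d_dnn_input_dimension_contract(self, rng):
        clf = build_1d_dnn(24)
        clf.trained = True
        with pytest.raises(ValidationError):
            clf.predict_proba(rng.random((3, 30)))


class TestConvOracle:
    def test_conv3d_matches_scipy_correlate(self, rng):
        """Single-channel valid 3-D convolution equals the scipy oracle."""
        conv = Conv3D(1, 1, (3, 3, 5), rng)
        x = rng.standard_normal((2, 7, 6, 9, 1)).astype(np.float32)
        out = conv.forward(x, train=False)[..., 0]
        kernel = conv.W[:, 0].reshape(3, 3, 5)
        for i in range(2):
            expected = correlate(x[i, :, :, :, 0], kernel, mode="valid") + conv.b[0]
            np.testing.assert_allclose(out[i], expected, rtol=2e-4, atol=2e-5)

    def test_conv2d_same_padding_matches_scipy(self, rng):
        conv = Conv2D(1, 1, (3, 3), rng)
        x = rng.standard_normal((1, 8, 8, 1)).astype(np.float32)
        out = conv.forward(x, train=False)[0, :, :, 0]
        kernel = conv.W[:, 0].reshape(3, 3)
        padded = np.pad(x[0, :, :, 0], 1)
        expected = correlate(padded, kernel, mode="valid") + conv.b[0]
        np.testing.assert_allclose(out, expected, rtol=2e-4, atol=2e-5)


class TestTraining:
    def test_separable_patches_fit_to_high_accuracy(self, rng):
        patches, labels = make_separable_patches(rng, patch=11)
        clf = build_hybrid_cnn(SMALL, seed=0)
        clf.fit(patches, labels, CFG)
        assert clf.loss_history[-1] < clf.loss_history[0]
        assert (clf.predict(patches) == labels).mean() >= 0.99

    def test_same_seed_is_bit_reproducible(self, rng):
        patches, labels = make_separable_patches(rng, n=40, patch=11)
        runs = []
        for _ in range(2):
            clf = build_hybrid_cnn(SMALL, seed=3)
            clf.fit(patches, labels, TrainConfig(epochs=3, batch_size=16, seed=3))
            runs.append(clf.predict_proba(patches))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)

    def test_single_class_training_rejected(self, rng):
        clf = build_hybrid_cnn(SMALL)
        with pytest.raises(ValidationError):
            clf.fit(rng.random((6, 11, 11, 12)), np.ones(6, dtype=int), CFG)

    def test_empty_training_set_rejected(self):
        clf = build_hybrid_cnn(SMALL)
        with pytest.raises(ValidationError):
            clf.fit(np.zeros((0, 11, 11, 12)), np.zeros(0, dtype=int), CFG)


class TestPredictContract:
    @pytest.fixture()
    def trained(self, rng):
        patches, labels = make_separable_patches(rng, n=40, patch=11)
        clf = build_hybrid_cnn(SMALL, seed=0)
        clf.fit(patches, labels, TrainConfig(epochs=4, batch_size=16, seed=0))
        return clf, patches

    def test_rows_sum_to_one(self, trained):
        clf, patches = trained
        np.testing.assert_allclose(clf.predict_proba(patches).sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_duplicated_patch_identical_rows(self, trained):
        clf, patches = trained
        dup = np.stack([patches[0], patches[0]])
        probs = clf.predict_proba(dup)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_permutation_equivariance(self, trained, rng):
        clf, patches = trained
        perm = rng.permutation(len(patches))
        np.testing.assert_allclose(clf.predict_proba(patches)[perm],
                                   clf.predict_proba(patches[perm]), atol=1e-6)

    def test_untrained_prediction_rejected(self):
        clf = build_hybrid_cnn(SMALL)
        with pytest.raises(StateError):
            clf.predict_proba(np.zeros((1, 11, 11, 12)))


class TestFeatureExtraction:
    def test_feature_dimension_is_flattened_last_conv(self, rng):
        patches, labels = make_separable_patches(rng, n=40, patch=11)
        clf = build_hybrid_cnn(SMALL, seed=0)
        clf.fit(patches, labels, TrainConfig(epochs=2, batch_size=16, seed=0))
        feats = extract_features(clf, patches)
        # last 2-D conv keeps 3x3 spatial extent with 16 filters (same padding)
        assert feats.shape == (40, 3 * 3 * SMALL.conv2d_layers[-1][0])

    def test_identical_patches_identical_features(self, rng):
        patches, labels = make_separable_patches(rng, n=40, patch=11)
        clf = build_hybrid_cnn(SMALL, seed=0)
        clf.fit(patches, labels, TrainConfig(epochs=2, batch_size=16, seed=0))
        feats = extract_features(clf, np.stack([patches[1], patches[1]]))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_features_feed_svm_without_reshaping(self, rng):
        patches, labels = make_separable_patches(rng, n=40, patch=11)
        clf = build_hybrid_cnn(SMALL, seed=0)
        clf.fit(patches, labels, TrainConfig(epochs=6, batch_size=16, seed=0))
        svm = train_svm(extract_features(clf, patches), labels)
        assert (svm.predict(extract_features(clf, patches)) == labels).mean() > 0.9

    def test_untrained_feature_extraction_rejected(self):
        with pytest.raises(StateError):
            build_hybrid_cnn(SMALL).extract_features(np.zeros((1, 11, 11, 12)))


class TestSvm:
    def test_separable_two_class_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(-3, 0.2, (20, 3)), rng.normal(3, 0.2, (20, 3))])
        y = np.repeat([1, 2], 20)
        svm = train_svm(x, y)
        assert (svm.predict(x) == y).all()

    def test_probability_rows_sum_to_one(self, rng):
        x = rng.normal(0, 1, (30, 4))
        y = rng.integers(1, 5, 30)
        y[:4] = [1, 2, 3, 4]
        svm = train_svm(x, y)
        np.testing.assert_allclose(svm.predict_proba(x).sum(axis=1), 1.0, atol=1e-9)

    def test_absent_class_gets_zero_probability(self, rng):
        x = np.vstack([rng.normal(-2, 0.2, (15, 2)), rng.normal(2, 0.2, (15, 2))])
        y = np.repeat([1, 3], 15)
        probs = train_svm(x, y).predict_proba(x)
        assert np.all(probs[:, 1] == 0) and np.all(probs[:, 3] == 0)

    def test_matches_analytic_max_margin_on_toy_set(self):
        """Hard-margin solution for +-x points is the hyperplane x1 = 0."""
        x = np.array([[-2.0, 0.0], [-1.0, 0.3], [1.0, -0.3], [2.0, 0.0]])
        y = np.array([1, 1, 2, 2])
        svm = train_svm(x, y)
        svm._svm.C = 1000.0  # effectively hard margin
        svm._svm.fit(x, y)
        w = svm._svm.coef_[0]
        b = svm._svm.intercept_[0]
        # analytic solution: w ∝ (1, 0.3)/|.|^2 normal, boundary through origin
        assert abs(b / np.linalg.norm(w)) < 0.1
        assert abs(w[1] / w[0]) < 0.45
        assert (svm.predict(np.array([[-0.5, 0.0], [0.5, 0.0]])) == [1, 2]).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_svm(rng.random((10, 2)), np.ones(10, dtype=int))
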