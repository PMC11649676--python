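"""Classifier-family contracts: reference layer stacks, training protocol,
prediction semantics, EMSF/matched-filter algebra and metric definitions."""

import numpy as np
import pytest

from eegdta import _nn
from eegdta import classifiers as cl

# The reference layer stacks, stated independently of the builder.
EXPECTED_LAYERS = {
    "mlp": [
        ("dense", {"units": 128, "activation": "relu"}),
        ("dense", {"units": 128, "activation": "relu"}),
        ("dense", {"units": 1, "activation": "sigmoid"}),
    ],
    "cnn": [
        ("conv2d", {"filters": 16, "kernel": (9, 9), "stride": (1, 1),
                    "activation": "relu"}),
        ("maxpool2d", {"pool": (2, 2)}),
        ("conv2d", {"filters": 16, "kernel": (9, 9), "stride": (1, 1),
                    "activation": "relu"}),
        ("maxpool2d", {"pool": (2, 2)}),
        ("flatten", {}),
        ("dense", {"units": 64, "activation": "relu"}),
        ("dense", {"units": 64, "activation": "relu"}),
        ("dense", {"units": 1, "activation": "sigmoid"}),
    ],
    "cnn_shallow": [
        ("conv2d", {"filters": 8, "kernel": (2, 2), "stride": (1, 1),
                    "activation": "relu"}),
        ("maxpool2d", {"pool": (10, 10)}),
        ("flatten", {}),
        ("dense", {"units": 1, "activation": "sigmoid"}),
    ],
    "cnn_lstm": [
        ("conv2d", {"filters": 8, "kernel": (2, 2), "stride": (1, 1),
                    "activation": "relu"}),
        ("maxpool2d", {"pool": (2, 2)}),
        ("conv2d", {"filters": 1, "kernel": (2, 2), "stride": (1, 1),
                    "activation": "relu"}),
        ("maxpool2d", {"pool": (2, 2)}),
        ("lstm", {"units": 8, "activation": "relu"}),
        ("dense", {"units": 1, "activation": "sigmoid"}),
    ],
}


class TestArchitectureAudit:
    @pytest.mark.parametrize("family", sorted(EXPECTED_LAYERS))
    def test_layer_stack_field_for_field(self, family):
        spec = cl.architecture_spec(family)
        assert [list(layer) for layer in spec.layers] == \
            [list(layer) for layer in EXPECTED_LAYERS[family]]

    def test_mlp_built_shape(self):
        net = cl.build_network(cl.architecture_spec("mlp"), (32, 500),
                               np.random.default_rng(0))
        dense = [l for l in net.layers if isinstance(l, _nn.Dense)]
        assert len(net.layers) == 3 and len(dense) == 3
        assert [d.W.shape for d in dense] == [(16000, 128), (128, 128),
                                              (128, 1)]
        assert dense[-1].activation == "sigmoid"

    def test_cnn_flattened_feature_length(self):
        # 32x500 -> conv9 -> 24x492 -> pool2 -> 12x246 -> conv9 -> 4x238
        # -> pool2 -> 2x119 x 16 filters = 3808 flat features
        net = cl.build_network(cl.architecture_spec("cnn"), (32, 500),
                               np.random.default_rng(0))
        first_dense = next(l for l in net.layers if isinstance(l, _nn.Dense))
        assert first_dense.W.shape[0] == 2 * 119 * 16

    def test_cnn_shallow_built_shape(self):
        # 32x500 -> conv2 -> 31x499 -> pool10 -> 3x49 x 8 = 1176
        net = cl.build_network(cl.architecture_spec("cnn_shallow"),
                               (32, 500), np.random.default_rng(0))
        conv = net.layers[0]
        assert isinstance(conv, _nn.Conv2D)
        assert conv.filters == 8 and conv.kernel == (2, 2)
        assert net.layers[1].pool == (10, 10)
        dense = net.layers[-1]
        assert dense.W.shape == (3 * 49 * 8, 1)

    def test_cnn_lstm_units_and_activation_override(self):
        net = cl.build_network(cl.architecture_spec("cnn_lstm"), (32, 500),
                               np.random.default_rng(0))
        lstm = next(l for l in net.layers if isinstance(l, _nn.LSTM))
        assert lstm.units == 8 and lstm.activation == "relu"

    def test_oversized_kernel_names_layer(self):
        with pytest.raises(cl.ConfigurationError, match="conv2d"):
            cl.build_network(cl.architecture_spec("cnn"), (4, 4),
                             np.random.default_rng(0))


@pytest.fixture(scope="module")
def toy_epochs():
    """Separable toy data: positives carry a negative ramp on channel 0."""
    rng = np.random.default_rng(0)
    n, c, t = 40, 4, 50
    X = rng.standard_normal((n, c, t))
    y = np.tile([0, 1], n // 2)
    X[y == 1, 0, :] += np.linspace(0, -4, t)
    return X, y


class TestTrainingProtocol:
    def test_fit_is_deterministic(self, toy_epochs):
        X, y = toy_epochs
        runs = [cl.MlpEpochClassifier(units=8, max_epochs=5,
                                      random_state=3).fit(X, y)
                for _ in range(2)]
        for a, b in zip(runs[0].net_.get_weights(),
                        runs[1].net_.get_weights()):
            assert np.array_equal(a, b)
        assert runs[0].validation_metrics_ == runs[1].validation_metrics_

    def test_single_class_rejected(self, toy_epochs):
        X, _ = toy_epochs
        with pytest.raises(ValueError):
            cl.MlpEpochClassifier().fit(X, np.zeros(len(X)))
        with pytest.raises(ValueError):
            cl.MatchedFilterLDA().fit(X, np.ones(len(X)))

    def test_validation_split_bounds(self, toy_epochs):
        X, y = toy_epochs
        with pytest.raises(cl.ConfigurationError):
            cl.MlpEpochClassifier(validation_split=1.5).fit(X, y)

    def test_separable_data_learned(self, toy_epochs):
        X, y = toy_epochs
        clf = cl.MlpEpochClassifier(units=16, max_epochs=40,
                                    random_state=0).fit(X, y)
        assert clf.validation_metrics_.accuracy >= 0.8

    def test_sklearn_params_roundtrip(self):
        clf = cl.CnnEpochClassifier(filters=4)
        params = clf.get_params()
        assert params["filters"] == 4
        clone = cl.CnnEpochClassifier(**params)
        assert clone.get_params() == params


class TestPrediction:
    def test_zeroed_output_layer_gives_half(self, toy_epochs):
        X, y = toy_epochs
        clf = cl.MlpEpochClassifier(units=8, max_epochs=1,
                                    random_state=0).fit(X, y)
        last = clf.net_.layers[-1]
        last.W = np.zeros_like(last.W)
        last.b = np.zeros_like(last.b)
        assert np.allclose(clf.predict_proba(X)[:, 1], 0.5)

    def test_batch_equals_per_epoch_and_order_invariant(self, toy_epochs):
        X, y = toy_epochs
        clf = cl.MlpEpochClassifier(units=8, max_epochs=3,
                                    random_state=0).fit(X, y)
        batch = clf.predict_proba(X)[:, 1]
        single = np.concatenate(
            [clf.predict_proba(X[i: i + 1])[:, 1] for i in range(len(X))])
        assert np.allclose(batch, single)
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.allclose(clf.predict_proba(X[perm])[:, 1], batch[perm])

    def test_shape_mismatch_rejected(self, toy_epochs):
        X, y = toy_epochs
        clf = cl.MatchedFilterLDA().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(X[:, :, :30])


class TestEmsf:
    def test_single_channel_effect_converges(self):
        rng = np.random.default_rng(0)
        n, c, t = 400, 8, 60
        X = rng.standard_normal((n, c, t))
        y = np.tile([0, 1], n // 2)
        effect = np.sin(np.linspace(0, np.pi, t)) * 5
        X[y == 1, 3, :] += effect
        w = cl.emsf_fit(X, y)
        assert abs(w[3]) > 0.95
        assert np.abs(np.delete(w, 3)).max() < 0.3

    def test_unit_norm_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5, 40))
        y = np.tile([0, 1], 30)
        X[y == 1, 1, :] += 2.0
        w1 = cl.emsf_fit(X, y)
        w2 = cl.emsf_fit(2.0 * X, y)
        assert np.linalg.norm(w1) == pytest.approx(1.0)
        assert np.allclose(np.abs(w1), np.abs(w2))

    def test_zero_effect_rejected(self):
        X = np.zeros((10, 3, 20))
        y = np.tile([0, 1], 5)
        with pytest.raises(ValueError, match="zero class effect"):
            cl.emsf_fit(X, y)

    def test_rms_weighting_mode(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 4, 30))
        y = np.tile([0, 1], 50)
        X[y == 1, 2, :] -= 3.0
        w = cl.emsf_fit(X, y, weighting="rms")
        assert np.linalg.norm(w) == pytest.approx(1.0)
        assert abs(w[2]) == np.abs(w).max()


class TestMatchedFilterLda:
    def test_template_self_correlation_is_one(self):
        template = np.sin(np.linspace(0, 3, 50))
        feat = cl._template_correlation(template[None, :], template)
        assert feat[0] == pytest.approx(1.0)

    def test_decision_matches_midpoint_threshold_rule(self, toy_epochs):
        """On its 1-D feature, balanced equal-variance LDA reduces to
        thresholding at the midpoint of the class means."""
        X, y = toy_epochs
        clf = cl.MatchedFilterLDA(random_state=0).fit(X, y)
        feat = clf._features(X).ravel()
        m0 = feat[clf.predict(X) == 0]
        # recompute the rule from training features
        from sklearn.model_selection import train_test_split
        Xtr, _, ytr, _ = train_test_split(X, y, test_size=0.2, stratify=y,
                                          random_state=0)
        ftr = clf._features(Xtr).ravel()
        mid = (ftr[ytr == 0].mean() + ftr[ytr == 1].mean()) / 2
        sign = 1 if ftr[ytr == 1].mean() > ftr[ytr == 0].mean() else -1
        rule = (sign * (feat - mid) > 0).astype(int)
        assert np.array_equal(clf.predict(X), rule)

    def test_high_separation_perfect_accuracy(self, toy_epochs):
        X, y = toy_epochs
        clf = cl.MatchedFilterLDA(random_state=1).fit(X, y)
        assert clf.validation_metrics_.accuracy >= 0.9


class TestMetrics:
    def test_perfect_prediction(self):
        m = cl.evaluate_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_f1_harmonic_mean(self):
        # 12 TP, 3 FP, 8 FN -> precision 0.8, recall 0.6
        y_true = [1] * 20 + [0] * 10
        y_pred = [1] * 12 + [0] * 8 + [1] * 3 + [0] * 7
        m = cl.evaluate_metrics(y_true, y_pred)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.8 * 0.6 / 1.4)

    def test_all_negative_flagged_not_nan(self):
        m = cl.evaluate_metrics([1, 0, 1], [0, 0, 0])
        assert m.precision == 0 and m.f1 == 0 and m.recall == 0
        assert m.degenerate

    def test_empty_or_mismatched_input(self):
        with pytest.raises(ValueError):
            cl.evaluate_metrics([], [])
        with pytest.raises(ValueError):
            cl.evaluate_metrics([1], [1, 0])


class TestPersistence:
    @pytest.mark.parametrize("factory", [
        lambda: cl.MlpEpochClassifier(units=8, max_epochs=3, random_state=0),
        lambda: cl.MatchedFilterLDA(random_state=0),
    ])
    def test_save_load_roundtrip(self, factory, toy_epochs, tmp_path):
        X, y = toy_epochs
        clf = factory().fit(X, y)
        path = tmp_path / "model.npz"
        cl.save_classifier(clf, path)
        loaded = cl.load_classifier(path)
        assert np.allclose(loaded.predict_proba(X), clf.predict_proba(X))
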