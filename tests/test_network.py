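import numpy as np
import pytest

from laminaseg import network as net
from laminaseg.network import (ConfigurationError, DataError, Network,
                               NetworkConfig, ProfileLayerClassifier,
                               accuracy_and_deviation, confidence,
                               cross_validate, degrade_resolution,
                               desk_config, median_frequency_weights, predict,
                               softmax, train, weighted_cross_entropy)
from laminaseg.synthetic import (SyntheticCortexSpec, _default_layers,
                                 generate_training_set)


class TestMedianFrequencyWeights:
    def test_uniform_frequencies_give_unit_weights(self):
        labels = np.repeat(np.arange(8), 25)
        np.testing.assert_allclose(median_frequency_weights(labels), 1.0)

    def test_annotated_proportions_weight_thin_layers(self):
        freqs = np.array([14.6, 7.5, 5.6, 20.8, 5.5, 14.8, 17.8, 13.4])
        counts = (freqs * 10).astype(int)
        labels = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        w = median_frequency_weights(labels)
        # median frequency is 14.0%; layer IV weight = 14.0/5.5
        assert w[4] == pytest.approx(14.0 / 5.5, rel=1e-3)
        assert w[4] == pytest.approx(2.545, abs=0.005)
        assert w[2] > 1.0 > w[3]  # thin II up-weighted, thick III down

    def test_scale_invariance(self):
        labels = np.concatenate([np.full(c, i) for i, c in
                                 enumerate([5, 3, 2, 8, 2, 6, 7, 5])])
        doubled = np.concatenate([labels, labels])
        np.testing.assert_allclose(median_frequency_weights(labels),
                                   median_frequency_weights(doubled))

    def test_absent_class_rejected(self):
        with pytest.raises(ConfigurationError, match=r"\[3\]"):
            median_frequency_weights(np.array([0, 1, 2, 4, 5, 6, 7]))


class TestWeightedCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        labels = np.array([0, 3, 7])
        probs = np.zeros((3, 8))
        probs[np.arange(3), labels] = 1.0
        assert weighted_cross_entropy(probs, labels, np.ones(8)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_ln8(self):
        probs = np.full((10, 8), 1 / 8)
        labels = np.arange(10) % 8
        assert weighted_cross_entropy(probs, labels, np.ones(8)) == \
            pytest.approx(np.log(8), rel=1e-9)

    def test_batch_matches_naive_loop(self, rng):
        probs = rng.dirichlet(np.ones(8), size=(64, 200)).transpose(0, 2, 1)
        labels = rng.integers(0, 8, (64, 200))
        weights = rng.uniform(0.5, 3.0, 8)
        naive = np.mean([
            weights[labels[b, t]] * -np.log(probs[b, labels[b, t], t])
            for b in range(64) for t in range(200)])
        assert weighted_cross_entropy(probs, labels, weights) == \
            pytest.approx(naive, abs=1e-6)

    def test_zero_probability_clamped(self):
        probs = np.zeros((1, 8))
        probs[0, 1] = 1.0
        loss = weighted_cross_entropy(probs, np.array([0]), np.ones(8))
        assert np.isfinite(loss)


class TestBuildNetwork:
    def test_forward_shape(self):
        model = Network(NetworkConfig(n_blocks=2, filter_size=9,
                                      n_feature_maps=8))
        out = model.forward(np.zeros((3, 2, 200)))
        assert out.shape == (3, 8, 200)

    def test_zero_input_finite_softmax(self):
        model = Network(NetworkConfig(n_blocks=2, filter_size=9,
                                      n_feature_maps=8))
        p = softmax(model.forward(np.zeros((1, 2, 200))), axis=1)
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-5)

    def test_hand_set_weights_match_closed_form(self):
        # single block, all filter sizes 1: the forward pass reduces to
        # per-point batchnorm -> relu -> two affine maps
        model = Network(NetworkConfig(n_blocks=1, filter_size=1,
                                      n_feature_maps=4))
        bn, relu, conv1, conv2 = model.layers
        conv1.w = np.arange(8, dtype=np.float32).reshape(4, 2, 1) * 0.1
        conv1.b = np.array([0.1, -0.2, 0.3, 0.0], dtype=np.float32)
        conv2.w = np.ones((8, 4, 1), dtype=np.float32) * 0.5
        conv2.b = np.zeros(8, dtype=np.float32)
        x = np.array([[[1.0] * 200, [2.0] * 200]])
        logits = model.forward(x, training=False)  # BN uses running stats
        xn = (x[0, :, 0] - bn.run_mean) / np.sqrt(bn.run_var + bn.eps)
        h = np.maximum(xn, 0)
        z1 = conv1.w[:, :, 0] @ h + conv1.b
        z2 = conv2.w[:, :, 0] @ z1 + conv2.b
        np.testing.assert_allclose(logits[0, :, 0], z2, rtol=1e-5)
        np.testing.assert_allclose(logits[0, :, 100], z2, rtol=1e-5)


def tiny_set(n, texture_sd=0.0, seed=0):
    spec = SyntheticCortexSpec(layer_specs=_default_layers(texture_sd))
    return generate_training_set(spec, n, seed=seed)


class TestTraining:
    def test_separable_set_reaches_high_accuracy(self):
        pset = tiny_set(150, texture_sd=0.0)
        cfg = desk_config(max_epochs=40, patience_epochs=15)
        model, hist = train(Network(cfg), pset.subset(np.arange(30, 150)),
                            pset.subset(np.arange(30)), cfg)
        assert max(hist.val_accuracy) >= 0.99

    def test_constant_accuracy_stops_after_patience(self):
        pset = tiny_set(30)
        cfg = NetworkConfig(n_blocks=1, filter_size=1, n_feature_maps=4,
                            learning_rate=0.0, batch_size=16,
                            patience_epochs=5, max_epochs=100, seed=0)
        _, hist = train(Network(cfg), pset.subset(np.arange(10, 30)),
                        pset.subset(np.arange(10)), cfg)
        # once the best epoch stops moving there are exactly `patience`
        # further evaluations before the stop
        assert hist.n_epochs == hist.best_epoch + cfg.patience_epochs + 1
        assert hist.n_epochs < cfg.max_epochs

    def test_seed_determinism(self):
        pset = tiny_set(40, texture_sd=0.05)
        cfg = NetworkConfig(n_blocks=2, filter_size=5, n_feature_maps=4,
                            learning_rate=0.05, batch_size=16,
                            patience_epochs=3, max_epochs=5, seed=7)
        runs = []
        for _ in range(2):
            model, hist = train(Network(cfg), pset.subset(np.arange(10, 40)),
                                pset.subset(np.arange(10)), cfg)
            runs.append((model.state(), hist.val_accuracy))
        assert runs[0][1] == runs[1][1]
        for k in runs[0][0]:
            np.testing.assert_array_equal(runs[0][0][k], runs[1][0][k])

    def test_empty_sets_rejected(self):
        pset = tiny_set(10)
        cfg = NetworkConfig(n_blocks=1, filter_size=1, n_feature_maps=2)
        with pytest.raises(DataError):
            train(Network(cfg), (pset.x[:0], pset.labels[:0]),
                  (pset.x, pset.labels), cfg)

    def test_loss_decreases_early(self):
        pset = tiny_set(60, texture_sd=0.05)
        cfg = NetworkConfig(n_blocks=2, filter_size=9, n_feature_maps=8,
                            learning_rate=0.05, batch_size=16,
                            patience_epochs=10, max_epochs=8, seed=1)
        _, hist = train(Network(cfg), pset.subset(np.arange(10, 60)),
                        pset.subset(np.arange(10)), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]


class TestPredictConfidence:
    def test_probability_simplex(self, rng):
        model = Network(NetworkConfig(n_blocks=1, filter_size=5,
                                      n_feature_maps=4))
        pm = predict(model, rng.normal(size=(5, 2, 200)))
        assert (pm.probs >= 0).all()
        np.testing.assert_allclose(pm.probs.sum(axis=1), 1.0, rtol=1e-5)

    def test_duplicated_profile_identical_prediction(self, rng):
        model = Network(NetworkConfig(n_blocks=1, filter_size=5,
                                      n_feature_maps=4))
        x = rng.normal(size=(1, 2, 200))
        pm = predict(model, np.concatenate([x, x]))
        np.testing.assert_array_equal(pm.probs[0], pm.probs[1])

    def test_wrong_length_rejected(self, rng):
        model = Network(NetworkConfig(n_blocks=1, filter_size=5,
                                      n_feature_maps=4))
        with pytest.raises(DataError, match="200"):
            predict(model, rng.normal(size=(1, 2, 100)))

    def test_fixed_weight_model_matches_forward_oracle(self):
        # width-1 linear network: argmax must equal the affine oracle's
        model = Network(NetworkConfig(n_blocks=1, filter_size=1,
                                      n_feature_maps=4))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 2, 200))
        pm = predict(model, x)
        bn, _, c1, c2 = model.layers
        xn = (x - bn.run_mean[None, :, None]) / np.sqrt(
            bn.run_var[None, :, None] + bn.eps)
        h = np.maximum(bn.gamma[None, :, None] * xn
                       + bn.beta[None, :, None], 0)
        z = np.einsum("oc,bcn->bon", c1.w[:, :, 0], h) + c1.b[None, :, None]
        z = np.einsum("oc,bcn->bon", c2.w[:, :, 0], z) + c2.b[None, :, None]
        np.testing.assert_array_equal(pm.argmax_labels, z.argmax(axis=1))

    def test_confidence_margins(self):
        probs = np.zeros((1, 8, 3))
        probs[0, :, 0] = [1, 0, 0, 0, 0, 0, 0, 0]          # one-hot -> 1.0
        probs[0, :, 1] = 1 / 8                              # uniform -> 0.0
        probs[0, :, 2] = [0.6, 0.3, 0.1, 0, 0, 0, 0, 0]     # -> 0.3
        pm = net.PredictionMatrix(probs, probs.argmax(axis=1))
        cm = confidence(pm)
        np.testing.assert_allclose(cm.per_point[0], [1.0, 0.0, 0.3],
                                   atol=1e-12)
        assert ((cm.per_vertex >= 0) & (cm.per_vertex <= 1)).all()


class TestAccuracyAndDeviation:
    def test_identical_labels(self):
        labels = np.sort(np.random.default_rng(0).integers(0, 8, (5, 200)),
                         axis=1)
        acc, dev = accuracy_and_deviation(labels, labels, 0.02)
        assert acc == 1.0
        np.testing.assert_allclose(dev, 0.0)

    def test_uniform_shift_gives_expected_deviation(self):
        base = np.repeat(np.arange(8), 25)[None, :]  # clean 8-class profile
        shifted = np.roll(base, 3, axis=1)
        shifted[:, :3] = 0
        _, dev = accuracy_and_deviation(shifted, base, 0.02)
        np.testing.assert_allclose(dev, 3 * 0.02, atol=1e-9)

    def test_matches_brute_force_loop(self, rng):
        pred = np.sort(rng.integers(0, 8, (10, 200)), axis=1)
        true = np.sort(rng.integers(0, 8, (10, 200)), axis=1)
        acc, _ = accuracy_and_deviation(pred, true, 1.0)
        manual = sum(int(pred[i, t] == true[i, t]) for i in range(10)
                     for t in range(200)) / 2000
        assert acc == pytest.approx(manual)


class TestCrossValidation:
    def test_partition_and_fold_count(self):
        pset = tiny_set(60, texture_sd=0.0)
        cfg = NetworkConfig(n_blocks=1, filter_size=5, n_feature_maps=4,
                            learning_rate=0.05, batch_size=16,
                            patience_epochs=1, max_epochs=2, seed=0)
        res = cross_validate(pset, cfg, k=5)
        assert len(res.fold_accuracies) == 5
        assert res.boundary_deviation_mm.shape == (7,)

    def test_k_below_three_rejected(self):
        pset = tiny_set(10)
        with pytest.raises(ConfigurationError):
            cross_validate(pset, NetworkConfig(), k=2)

    def test_shuffled_labels_give_chance_level(self):
        pset = tiny_set(60, texture_sd=0.05, seed=2)
        rng = np.random.default_rng(0)
        shuffled = pset.labels.copy()
        rng.shuffle(shuffled.reshape(-1))  # destroys intensity-label link
        pset.labels = np.sort(shuffled, axis=1)  # keep monotone structure
        cfg = NetworkConfig(n_blocks=1, filter_size=9, n_feature_maps=4,
                            learning_rate=0.05, batch_size=16,
                            patience_epochs=2, max_epochs=4, seed=0)
        res = cross_validate(pset, cfg, k=4)
        assert res.mean < 0.45  # far below the >0.95 of learnable data


class TestResolutionDegradation:
    def test_native_resolution_identity(self, rng):
        x = rng.normal(size=(3, 2, 200))
        out = degrade_resolution(x, 4.1, 20.0)  # >= 200 voxels per profile
        np.testing.assert_array_equal(out, x)

    def test_coarse_resolution_collapses_detail(self, rng):
        x = rng.normal(size=(2, 2, 200))
        out = degrade_resolution(x, 3.5, 1000.0)
        # ~4 independent samples remain: piecewise-linear through 4 knots
        # (each knot bends the curve over at most 2 grid points)
        for c in range(2):
            d2 = np.abs(np.diff(out[0, c], 2))
            assert (d2 > 1e-9).sum() <= 2 * 4


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted

        clf = ProfileLayerClassifier(n_blocks=1, filter_size=5,
                                     n_feature_maps=4, learning_rate=0.05,
                                     patience_epochs=2, max_epochs=3)
        params = clf.get_params()
        assert params["filter_size"] == 5
        clf2 = clf.set_params(max_epochs=2)
        assert clf2.max_epochs == 2
        with pytest.raises(Exception):
            check_is_fitted(clf, "network_")

    def test_fit_predict_shapes_and_score(self):
        pset = tiny_set(100, texture_sd=0.0)
        clf = ProfileLayerClassifier(n_blocks=3, filter_size=25,
                                     n_feature_maps=12, learning_rate=0.1,
                                     batch_size=64, patience_epochs=8,
                                     max_epochs=25, random_state=0)
        clf.fit(pset.x, pset.labels)
        proba = clf.predict_proba(pset.x[:5])
        assert proba.shape == (5, 8, 200)
        labels = clf.predict(pset.x[:5])
        assert labels.shape == (5, 200)
        assert clf.score(pset.x, pset.labels) > 0.95
        assert clf.n_epochs_ == clf.history_.n_epochs

    def test_bad_shapes_rejected(self):
        clf = ProfileLayerClassifier()
        with pytest.raises(DataError):
            clf.fit(np.zeros((4, 2, 100)), np.zeros((4, 100)))


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = Network(NetworkConfig(n_blocks=2, filter_size=7,
                                      n_feature_maps=6))
        x = rng.normal(size=(2, 2, 200))
        before = predict(model, x).probs
        path = tmp_path / "model.npz"
        model.save(path)
        after = predict(Network.load(path), x).probs
        np.testing.assert_allclose(before, after, atol=1e-6)
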