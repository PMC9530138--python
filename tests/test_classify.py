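import numpy as np
import pytest

import strainspeech as ss
from strainspeech import nn
from strainspeech.classify import (ConvSpec, build_model, correlation_classify,
                                   correlation_cv, load_checkpoint,
                                   output_shape, save_checkpoint, svm_classify)


def test_convspec_validation():
    with pytest.raises(ValueError):
        ConvSpec(conv_channels=(8, 8, 8))
    with pytest.raises(ValueError):
        ConvSpec(fc_sizes=(64,))
    with pytest.raises(ValueError):
        ConvSpec(axis_order="xyz")


def test_output_shape_default_mapping():
    spec = ConvSpec()
    shapes, flat = output_shape(spec, (2, 4, 600))
    # stride-1 same-padded layers preserve the shape; Conv3 halves H and T
    assert shapes[0] == (2, 4, 600)
    assert shapes[2] == (1, 4, 300)
    assert shapes[-1] == (1, 4, 300)
    assert flat == 64 * 1 * 4 * 300 == 76800


def test_output_shape_alternative_axis_reading():
    shapes, _ = output_shape(ConvSpec(axis_order="thw"), (2, 4, 600))
    # with the (T, H, W) reading Conv3's unit kernel entry falls on H
    assert shapes[2] == (2, 2, 300)


def test_build_model_structure_and_determinism():
    spec = ConvSpec(conv_channels=(2, 2, 2, 2, 2, 2, 2), fc_sizes=(8, 4))
    net1 = build_model(spec, 3, (2, 4, 20), seed=7)
    net2 = build_model(spec, 3, (2, 4, 20), seed=7)
    convs = [l for l in net1.layers if isinstance(l, nn.Conv3d)]
    fcs = [l for l in net1.layers if isinstance(l, nn.Linear)]
    assert len(convs) == 7 and len(fcs) == 3
    flattens = [l for l in net1.layers if isinstance(l, nn.Flatten)]
    assert len(flattens) == 1 and net1.layers[-6] is flattens[0]
    for k, v in net1.state_arrays().items():
        np.testing.assert_array_equal(v, net2.state_arrays()[k])
    logits = net1.forward(np.zeros((1, 1, 2, 4, 20)))
    assert np.all(np.isfinite(logits))


def test_architecture_conformance_across_lengths(cnn_params):
    """Shape arithmetic agrees with real forward activations layer by layer."""
    spec = ConvSpec(conv_channels=cnn_params["conv_channels"],
                    fc_sizes=cnn_params["fc_sizes"])
    for T in (60, 300):
        shapes, flat = output_shape(spec, (2, 4, T))
        net = build_model(spec, 2, (2, 4, T), seed=0)
        outs = net.forward_collect(np.zeros((1, 1, 2, 4, T)))
        for i in range(7):
            assert outs[3 * i].shape[2:] == shapes[i]
        assert outs[21].shape[1] == flat


class TestCNNClassifier:
    def test_overfits_two_separated_classes(self, cnn_params):
        cfg = ss.SimConfig(n_classes=2, reps_per_class=10, n_subjects=1,
                           noise_sd=0.02, seed=2)
        recs = ss.synth_dataset(cfg)
        X = ss.SignalPreprocessor(out_len=60).fit_transform(recs)
        y = np.array([r.class_id for r in recs])
        clf = ss.Conv3DWordClassifier(**cnn_params, epochs=25, random_state=0)
        clf.fit(X, y)
        assert clf.training_log_[-1] < clf.training_log_[0]
        np.testing.assert_array_equal(clf.predict(X), y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(proba, clf.predict_proba(X))
        feats = clf.extract_features(X)
        assert feats.shape == (20, cnn_params["fc_sizes"][1])

    def test_training_bit_reproducible(self, cnn_params):
        cfg = ss.SimConfig(n_classes=2, reps_per_class=4, n_subjects=1, seed=3)
        recs = ss.synth_dataset(cfg)
        X = ss.SignalPreprocessor(out_len=40).fit_transform(recs)
        y = np.array([r.class_id for r in recs])
        runs = [ss.Conv3DWordClassifier(**cnn_params, epochs=4, random_state=5).fit(X, y)
                for _ in range(2)]
        assert runs[0].training_log_ == runs[1].training_log_
        np.testing.assert_array_equal(runs[0].predict_proba(X),
                                      runs[1].predict_proba(X))

    def test_single_class_rejected(self, cnn_params):
        X = np.zeros((4, 1, 2, 4, 20))
        with pytest.raises(ValueError):
            ss.Conv3DWordClassifier(**cnn_params, epochs=1).fit(X, np.zeros(4))

    def test_shape_mismatch_rejected(self, cnn_params):
        X = np.random.default_rng(0).normal(size=(6, 1, 2, 4, 20))
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = ss.Conv3DWordClassifier(**cnn_params, epochs=1).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(np.zeros((1, 1, 2, 4, 30)))

    def test_checkpoint_roundtrip(self, cnn_params, tmp_path):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 1, 2, 4, 20))
        y = np.array([0, 1, 2, 3] * 2)
        clf = ss.Conv3DWordClassifier(**cnn_params, epochs=3).fit(X, y)
        path = tmp_path / "model.npz"
        save_checkpoint(clf, path)
        loaded = load_checkpoint(path)
        np.testing.assert_allclose(loaded.predict_proba(X), clf.predict_proba(X),
                                   atol=1e-6)
        np.testing.assert_array_equal(loaded.classes_, clf.classes_)


class TestCorrelation:
    def test_identical_query_matches_with_similarity_one(self):
        refs = np.eye(3)
        labels = np.array([0, 1, 2])
        clf = ss.CorrelationWordClassifier().fit(refs, labels)
        sim = clf.similarity(refs[1:2])
        assert sim[0, 1] == pytest.approx(1.0)
        assert clf.predict(refs[1:2])[0] == 1

    def test_orthogonal_query_tie_breaks_to_lowest_class(self):
        refs = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0], [0, 0, 1.0, 0]])
        pred = correlation_classify(refs, [2, 0, 1], [[0, 0, 0, 1.0]])
        assert pred[0] == 0

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        refs = rng.normal(size=(5, 30))
        labels = np.arange(5)
        queries = rng.normal(size=(50, 30))
        pred = correlation_classify(refs, labels, queries)
        for q, p in zip(queries, pred):
            sims = [q @ r / (np.linalg.norm(q) * np.linalg.norm(r)) for r in refs]
            assert p == labels[int(np.argmax(sims))]

    def test_duplicate_reference_class_rejected(self):
        with pytest.raises(ValueError):
            correlation_classify(np.eye(3), [0, 0, 1], np.eye(3))

    def test_zero_norm_rejected(self):
        refs = np.array([[1.0, 0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            ss.CorrelationWordClassifier().fit(refs, [0, 1])

    def test_cv_noiseless_is_perfect(self, noiseless_data):
        X, y = noiseless_data
        groups = np.tile(np.arange(20), 5)  # rep index = reference group
        accs, mean = correlation_cv(X, y, groups)
        assert len(accs) == 20
        assert mean == pytest.approx(1.0)

    def test_cv_two_groups_and_missing_class(self):
        X = np.vstack([np.eye(3), np.eye(3) + 0.01])
        y = np.array([0, 1, 2, 0, 1, 2])
        accs, mean = correlation_cv(X, y, [0, 0, 0, 1, 1, 1])
        assert len(accs) == 2
        assert mean == pytest.approx(np.mean(accs))
        with pytest.raises(ValueError):
            correlation_cv(X, y, [0, 0, 1, 1, 1, 1])


class TestSVM:
    def test_separable_data_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(3, 0.1, (20, 5))])
        y = np.repeat([0, 1], 20)
        pred = svm_classify(X[::2], y[::2], X[1::2])
        np.testing.assert_array_equal(pred, y[1::2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.SVMWordClassifier().fit(np.zeros((3, 4)), np.zeros(3))

    def test_deterministic(self, noisy_data):
        X, y = noisy_data
        p1 = svm_classify(X[:60], y[:60], X[60:80])
        p2 = svm_classify(X[:60], y[:60], X[60:80])
        np.testing.assert_array_equal(p1, p2)
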