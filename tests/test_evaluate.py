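import itertools

import numpy as np
import pytest

import strainspeech as ss
from strainspeech.evaluate import (channel_ablation, confusion_matrix,
                                   cross_validate, kfold_split, learning_curve,
                                   mask_channels, snr, transfer_adapt)


class TestKFold:
    def test_partition_properties(self):
        y = np.repeat(np.arange(5), 20)
        folds = kfold_split(y, k=5, seed=3)
        assert [len(f) for f in folds] == [20] * 5
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(100))
        for a, b in itertools.combinations(folds, 2):
            assert np.intersect1d(a, b).size == 0
        # stratified: every fold holds every class
        for f in folds:
            assert np.unique(y[f]).size == 5

    def test_seeded_reproducibility(self):
        y = np.repeat(np.arange(4), 8)
        f1 = kfold_split(y, k=4, seed=9)
        f2 = kfold_split(y, k=4, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)
        f3 = kfold_split(y, k=4, seed=10)
        assert any(not np.array_equal(a, b) for a, b in zip(f1, f3))

    def test_errors(self):
        with pytest.raises(ValueError):
            kfold_split(np.array([0, 1]), k=5)
        with pytest.raises(ValueError):
            kfold_split(np.repeat([0, 1], 2), k=3)


class TestCrossValidate:
    def test_noiseless_correlation_is_perfect(self, noiseless_data):
        X, y = noiseless_data
        report = cross_validate(lambda: ss.CorrelationWordClassifier(), X, y,
                                k=5, seed=0)
        assert report.fold_accuracies == [100.0] * 5
        assert report.mean_accuracy == 100.0
        assert np.sum(report.confusion) == y.size
        np.testing.assert_array_equal(np.diag(report.confusion), 20)

    def test_mean_is_mean_of_folds_and_totals(self, noisy_data):
        X, y = noisy_data
        report = cross_validate(lambda: ss.CorrelationWordClassifier(), X, y,
                                k=5, seed=1)
        assert report.mean_accuracy == pytest.approx(np.mean(report.fold_accuracies))
        assert np.sum(report.confusion) == y.size

    def test_report_deterministic(self, noisy_data):
        X, y = noisy_data
        r1 = cross_validate(lambda: ss.SVMWordClassifier(), X, y, k=5, seed=2)
        r2 = cross_validate(lambda: ss.SVMWordClassifier(), X, y, k=5, seed=2)
        assert r1.to_json() == r2.to_json()


class TestLearningCurve:
    def test_entry_per_size_and_full_pool_equals_single_run(self, noisy_data):
        X, y = noisy_data
        factory = lambda: ss.CorrelationWordClassifier()
        res = learning_curve(factory, X, y, sizes=[10, 40, 80], repeats=2,
                             k=5, seed=4)
        assert len(res["mean_accuracy"]) == 3
        folds = kfold_split(y, k=5, seed=4)
        pool = np.setdiff1d(np.arange(y.size), folds[-1])
        full = learning_curve(factory, X, y, sizes=[pool.size], repeats=1,
                              k=5, seed=4)
        clf = factory().fit(X[pool], y[pool])
        direct = 100.0 * np.mean(clf.predict(X[folds[-1]]) == y[folds[-1]])
        assert full["mean_accuracy"][0] == pytest.approx(direct)

    def test_monotone_trend_on_separable_data(self, noiseless_data):
        X, y = noiseless_data
        res = learning_curve(lambda: ss.SVMWordClassifier(), X, y,
                             sizes=[5, 60], repeats=5, k=5, seed=0)
        assert res["mean_accuracy"][-1] >= res["mean_accuracy"][0]

    def test_empty_sizes_rejected(self, noisy_data):
        X, y = noisy_data
        with pytest.raises(ValueError):
            learning_curve(lambda: ss.SVMWordClassifier(), X, y, sizes=[])


class TestAblation:
    def test_subset_counts(self, noisy_data):
        X, y = noisy_data
        factory = lambda: ss.CorrelationWordClassifier()
        res8 = channel_ablation(factory, X, y, 8, seed=0)
        assert res8["n_subsets"] == 1
        res2 = channel_ablation(factory, X, y, 2, seed=0, mode="mask_only")
        assert res2["n_subsets"] == 28

    def test_mask_zeroes_exactly_the_complement(self, noisy_data):
        X, _ = noisy_data
        Xm = mask_channels(X, keep=[2, 3])
        from strainspeech.preprocess import DEFAULT_CHANNEL_MAP
        for (row, col), ch in DEFAULT_CHANNEL_MAP.items():
            block = Xm[:, :, row, col, :]
            if ch in (2, 3):
                np.testing.assert_array_equal(block, X[:, :, row, col, :])
            else:
                np.testing.assert_array_equal(block, 0.0)

    def test_invalid_inputs(self, noisy_data):
        X, y = noisy_data
        factory = lambda: ss.CorrelationWordClassifier()
        with pytest.raises(ValueError):
            channel_ablation(factory, X, y, 0)
        with pytest.raises(ValueError):
            channel_ablation(factory, X, y, 2, subsets=[(0, 1), (1, 0)])


class TestConfusion:
    def test_direct_counting(self):
        m = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(m, [[1, 1], [0, 1]])

    def test_perfect_is_diagonal_with_class_counts(self):
        y = np.repeat([0, 1, 2], [3, 4, 5])
        m = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(np.diag(m), [3, 4, 5])
        np.testing.assert_array_equal(m.sum(axis=1), [3, 4, 5])

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)
        with pytest.raises(ValueError):
            confusion_matrix([0], [0, 1], 2)


@pytest.fixture(scope="module")
def fitted(cnn_params, noisy_data):
    X, y = noisy_data
    clf = ss.Conv3DWordClassifier(**cnn_params, epochs=10, random_state=0)
    return clf.fit(X[::2], y[::2]), X, y


class TestTransfer:
    def test_size_zero_is_identity_and_conv_frozen(self, fitted):
        model, X, y = fitted
        before = {k: v.copy() for k, v in model.model_.state_arrays().items()}
        res = transfer_adapt(model, X[1::2], y[1::2], X[1::2], y[1::2],
                             sizes_per_class=(0, 2), epochs=3, seed=0)
        base_acc = 100.0 * np.mean(model.predict(X[1::2]) == y[1::2])
        assert res["accuracy"][0] == pytest.approx(base_acc)
        # the original model's conv parameters are untouched
        for k, v in model.model_.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])
        # the adapted copy keeps conv weights bit-identical, FC changed
        adapted = res["adapted_model"].model_.state_arrays()
        changed = []
        for k, v in adapted.items():
            layer_idx = int(k.split(".")[0][5:])
            if layer_idx < 21:  # conv stack
                np.testing.assert_array_equal(v, before[k])
            else:
                changed.append(not np.array_equal(v, before[k]))
        assert any(changed)

    def test_unknown_class_rejected(self, fitted):
        model, X, y = fitted
        with pytest.raises(ValueError):
            transfer_adapt(model, X[:4], np.full(4, 99), X[:4], y[:4],
                           sizes_per_class=(1,))


class TestSNR:
    def test_identity_and_homogeneity(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=500)
        assert snr(seg, seg) == pytest.approx(1.0)
        assert snr(2 * seg, seg) == pytest.approx(2.0)

    def test_sinusoid_against_closed_form(self):
        # sinusoid of amplitude sqrt(2) has unit RMS
        rng = np.random.default_rng(1)
        t = np.arange(10_000)
        active = np.sqrt(2) * np.sin(2 * np.pi * t / 50)
        rest = rng.normal(0, 1, 10_000)
        assert snr(active, rest) == pytest.approx(1.0, abs=0.05)

    def test_zero_rest_rejected(self):
        with pytest.raises(ValueError):
            snr([1.0], [0.0, 0.0])
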