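import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import strainspeech as ss
from strainspeech.preprocess import (DEFAULT_CHANNEL_MAP, PreprocessConfig,
                                     assemble_tensor, minmax_normalize,
                                     preprocess_record, savgol_smooth,
                                     to_fixed_grid)
from strainspeech.simulate import StrainRecord


def savgol_center_weights(window: int, polyorder: int) -> np.ndarray:
    """Independent oracle: solve the centered least-squares fit directly.

    Fitting a degree-p polynomial to samples at offsets -m..m and reading
    the value at offset 0 is a linear map; its weights are the first row of
    (A^T A)^{-1} A^T with A the Vandermonde matrix of the offsets.
    """
    m = window // 2
    offsets = np.arange(-m, m + 1)
    A = np.vander(offsets, polyorder + 1, increasing=True)
    return np.linalg.pinv(A)[0]


class TestMinmax:
    def test_examples(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(minmax_normalize([5, 5, 5]), [0, 0, 0])

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(size=100)
        once = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(once), once)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            minmax_normalize([1.0, np.nan])
        with pytest.raises(ValueError):
            minmax_normalize([np.inf, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_range(self, xs):
        out = minmax_normalize(xs)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestSavgol:
    def test_interpolating_filter_is_identity(self):
        x = np.random.default_rng(1).normal(size=50)
        np.testing.assert_allclose(savgol_smooth(x, 5, 4), x, atol=1e-9)

    def test_polynomial_reproduction(self):
        t = np.linspace(0, 1, 101)
        quad = 3 * t ** 2 - 2 * t + 0.5
        out = savgol_smooth(quad, 11, 2)
        np.testing.assert_allclose(out[5:-5], quad[5:-5], atol=1e-12)

    def test_center_weights_match_least_squares_oracle(self):
        expected = np.array([-3, 12, 17, 12, -3]) / 35.0
        oracle = savgol_center_weights(5, 2)
        np.testing.assert_allclose(oracle, expected, atol=1e-12)
        # impulse response of the implementation reveals its weights
        impulse = np.zeros(11)
        impulse[5] = 1.0
        out = savgol_smooth(impulse, 5, 2)
        np.testing.assert_allclose(out[3:8], expected[::-1], atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(5, 2), (7, 3), (15, 3), (9, 5)])
    def test_dc_preservation(self, window, polyorder):
        const = np.full(50, 3.7)
        np.testing.assert_allclose(savgol_smooth(const, window, polyorder), const)

    def test_validation(self):
        x = np.zeros(20)
        with pytest.raises(ValueError):
            savgol_smooth(x, 4, 2)
        with pytest.raises(ValueError):
            savgol_smooth(x, 5, 5)
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(3), 5, 2)


class TestFixedGrid:
    def test_identity_on_grid(self):
        x = np.random.default_rng(2).normal(size=600)
        np.testing.assert_array_equal(to_fixed_grid(x, 300.0, 600, 2.0), x)

    def test_constant_and_ramp(self):
        np.testing.assert_allclose(to_fixed_grid(np.full(600, 2.5), 300, 123, 2.0), 2.5)
        ramp = np.arange(600, dtype=float)
        down = to_fixed_grid(ramp, 300.0, 300, 2.0)
        np.testing.assert_allclose(down, np.arange(300) * 2.0, atol=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            to_fixed_grid([1.0], 300, 10, 2.0)


class TestAssemble:
    def test_shape_and_mapping(self):
        channels = np.arange(8)[:, None] * np.ones((1, 600))
        t = assemble_tensor(channels)
        assert t.values.shape == (1, 2, 4, 600)
        # 1-based channel 3 = index 2 = site S2 horizontal -> (row 0, col 1)
        assert DEFAULT_CHANNEL_MAP[(0, 1)] == 2
        np.testing.assert_allclose(t.values[0, 0, 1], 2.0)

    def test_bijection(self):
        rng = np.random.default_rng(3)
        channels = rng.normal(size=(8, 40))
        t = assemble_tensor(channels)
        np.testing.assert_array_equal(t.channels(), channels)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            assemble_tensor(np.zeros((7, 10)))


class TestPipeline:
    def _record(self, rng=None, scale=1.0):
        rng = rng or np.random.default_rng(4)
        return StrainRecord(scale * rng.normal(size=(8, 600)), class_id=0)

    def test_constant_record_all_zero(self):
        rec = StrainRecord(np.ones((8, 600)), class_id=0)
        out = preprocess_record(rec, PreprocessConfig(out_len=100))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_output_range_and_finite(self):
        out = preprocess_record(self._record(), PreprocessConfig(out_len=100))
        assert np.all(np.isfinite(out.values))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_both_stage_orders(self):
        rec = self._record()
        a = preprocess_record(rec, PreprocessConfig(normalize_first=True, out_len=100))
        b = preprocess_record(rec, PreprocessConfig(normalize_first=False, out_len=100))
        for v in (a.values, b.values):
            assert v.min() >= 0.0 and v.max() <= 1.0
        assert not np.allclose(a.values, b.values)

    def test_approximate_idempotence(self):
        """Re-running the pipeline on already-processed data changes it only
        marginally: normalization and regridding are exact fixed points and
        the smoother is near-idempotent on already-smooth signals."""
        cfg = ss.SimConfig(n_classes=5, reps_per_class=10, n_subjects=1,
                           noise_sd=0.02, seed=9)
        pcfg = PreprocessConfig(out_len=600)
        devs = []
        for rec in ss.synth_dataset(cfg):
            once = preprocess_record(rec, pcfg)
            again = preprocess_record(
                StrainRecord(once.channels(), rec.class_id), pcfg)
            devs.append(np.max(np.abs(again.values - once.values)))
        # re-smoothing attenuates the sharpest peaks by at most ~10% of the
        # [0, 1] range; the other stages are exact fixed points
        assert np.max(devs) < 0.15

    def test_preprocessor_transformer(self):
        cfg = ss.SimConfig(n_classes=3, reps_per_class=2, n_subjects=1, seed=1)
        recs = ss.synth_dataset(cfg)
        pre = ss.SignalPreprocessor(out_len=50)
        X = pre.fit_transform(recs)
        assert X.shape == (6, 1, 2, 4, 50)
        assert pre.get_params()["out_len"] == 50
        np.testing.assert_array_equal(X, pre.transform(recs))


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(savgol_window=10)
    with pytest.raises(ValueError):
        PreprocessConfig(savgol_window=5, savgol_polyorder=5)
    with pytest.raises(ValueError):
        PreprocessConfig(out_len=1)
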