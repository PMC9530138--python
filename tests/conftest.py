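import numpy as np
import pytest

import strainspeech as ss

# Desk-scale CNN: same architecture geometry as the full model, narrower
# channels and shorter input so CPU training stays in seconds.
CNN_PARAMS = dict(conv_channels=(4, 8, 8, 8, 8, 16, 16), fc_sizes=(64, 32),
                  batch_size=8, learning_rate=2e-3)
OUT_LEN = 60


def tensors_from(records):
    X = ss.SignalPreprocessor(out_len=OUT_LEN).fit_transform(records)
    y = np.array([r.class_id for r in records])
    return X, y


@pytest.fixture(scope="session")
def cnn_params():
    return dict(CNN_PARAMS)


@pytest.fixture(scope="session")
def noiseless_data():
    """5 classes x 20 reps with every noise source off: repetitions of a
    class are identical, so the task is perfectly separable."""
    cfg = ss.SimConfig(n_classes=5, reps_per_class=20, n_subjects=1,
                       noise_sd=0.0, time_jitter_sd=0.0, amp_jitter_sd=0.0,
                       drift_amplitude=0.0, seed=42)
    return tensors_from(ss.synth_dataset(cfg))


@pytest.fixture(scope="session")
def noisy_data():
    """Same task with realistic jitter and sensor noise."""
    cfg = ss.SimConfig(n_classes=5, reps_per_class=20, n_subjects=1,
                       noise_sd=0.05, seed=11)
    return tensors_from(ss.synth_dataset(cfg))


@pytest.fixture(scope="session")
def planted_window_setup():
    """Data whose class information is confined to a 20%-of-duration window
    on the site-S2 channels, plus a CNN trained on part of it."""
    window = (0.8, 1.2)
    channels = (2, 3)
    cfg = ss.SimConfig(n_classes=4, reps_per_class=12, n_subjects=1,
                       noise_sd=0.03, seed=7)
    templates = ss.plant_discriminative_window(cfg, window, channels)
    X, y = tensors_from(ss.synth_dataset(cfg, templates))
    idx = np.random.default_rng(0).permutation(y.size)
    train_idx, test_idx = idx[:28], idx[28:]
    model = ss.Conv3DWordClassifier(**CNN_PARAMS, epochs=40, random_state=0)
    model.fit(X[train_idx], y[train_idx])
    return {"X": X, "y": y, "model": model, "window": window,
            "channels": channels, "test_idx": test_idx}
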