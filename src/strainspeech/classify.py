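"""Word classifiers: the 3D CNN and the correlation / SVM baselines.

The main model is a compact 3D convolutional network over the
(1, 2, 4, T) strain tensor: seven convolution layers, each followed by
instance normalization and ReLU, with no pooling (Conv3 alone downsamples,
kernel (3,1,3), padding (1,0,1), stride (2,1,2)); the Conv7 output is
flattened into three fully connected layers (ReLU after FC1 and FC2, linear
output), trained with softmax cross-entropy and Adam.

Baselines: a nearest-template cosine-similarity classifier (each query is
assigned the class of the most similar reference recording) and a linear
support-vector machine on the flattened preprocessed tensors.

All classifiers are sklearn-style estimators (``fit`` / ``predict`` /
``get_params``) so they compose with sklearn model selection; the
module-level functions are thin wrappers kept for script use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from . import nn
from .nn import Network, conv3d_out_shape

__all__ = [
    "ConvSpec",
    "TrainConfig",
    "output_shape",
    "build_model",
    "Conv3DWordClassifier",
    "CorrelationWordClassifier",
    "SVMWordClassifier",
    "train",
    "predict",
    "extract_features",
    "correlation_classify",
    "correlation_cv",
    "svm_classify",
    "save_checkpoint",
    "load_checkpoint",
]

# fixed architecture geometry, printed triples in (H, W, T) order
_KERNELS = [(3, 3, 3)] * 7
_PADS = [(1, 1, 1)] * 7
_STRIDES = [(1, 1, 1)] * 7
_KERNELS[2], _PADS[2], _STRIDES[2] = (3, 1, 3), (1, 0, 1), (2, 1, 2)

N_CONV_LAYERS = 7
N_FC_LAYERS = 3


def _map_axes(triple: tuple, axis_order: str) -> tuple:
    """Interpret a printed (a, b, c) triple on the tensor's (H, W, T) axes.

    'hwt' (default): triple is already (H, W, T).
    'thw': triple is read as (T, H, W) — the alternative interpretation in
    which the unit middle entry of Conv3's kernel falls on H instead of W.
    """
    if axis_order == "hwt":
        return triple
    if axis_order == "thw":
        t, h, w = triple
        return (h, w, t)
    raise ValueError(f"axis_order must be 'hwt' or 'thw', got {axis_order!r}")


@dataclass(frozen=True)
class ConvSpec:
    """Architecture hyperparameters of the 3D CNN.

    Kernel/padding/stride geometry is fixed by the architecture; only the
    channel widths, the two hidden FC sizes and the kernel-axis reading are
    configurable. Default widths are sized for CPU training.
    """

    conv_channels: tuple = (8, 16, 16, 32, 32, 64, 64)
    fc_sizes: tuple = (256, 128)
    axis_order: str = "hwt"

    def __post_init__(self) -> None:
        if len(self.conv_channels) != N_CONV_LAYERS:
            raise ValueError(f"conv_channels must have {N_CONV_LAYERS} entries")
        if any(int(c) < 1 for c in self.conv_channels):
            raise ValueError("conv_channels must be positive")
        if len(self.fc_sizes) != N_FC_LAYERS - 1:
            raise ValueError("fc_sizes must give the two hidden FC widths")
        if any(int(c) < 1 for c in self.fc_sizes):
            raise ValueError("fc_sizes must be positive")
        _map_axes((1, 2, 3), self.axis_order)  # validate axis_order

    def layer_geometry(self, i: int) -> tuple:
        """(kernel, pad, stride) of conv layer ``i`` (0-based), on (H, W, T)."""
        return (_map_axes(_KERNELS[i], self.axis_order),
                _map_axes(_PADS[i], self.axis_order),
                _map_axes(_STRIDES[i], self.axis_order))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def output_shape(spec: ConvSpec, input_shape: tuple) -> tuple:
    """Per-layer (H, W, T) shapes and the flatten length.

    Pure shape arithmetic, n_out = floor((n_in + 2p - k)/s) + 1 per axis;
    independent of the actual forward pass (which must agree with it).
    """
    shapes = []
    sp = tuple(int(v) for v in input_shape)
    if len(sp) != 3:
        raise ValueError("input_shape must be (H, W, T)")
    for i in range(N_CONV_LAYERS):
        kernel, pad, stride = spec.layer_geometry(i)
        sp = conv3d_out_shape(sp, kernel, pad, stride)
        shapes.append(sp)
    flatten_len = int(spec.conv_channels[-1]) * int(np.prod(shapes[-1]))
    return shapes, flatten_len


def build_model(spec: ConvSpec, n_classes: int, input_shape: tuple,
                seed: int = 0) -> Network:
    """Untrained network: 7x (conv3d + instance norm + ReLU), flatten, 3 FC."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3DC]))
    layers = []
    cin = 1
    for i, cout in enumerate(spec.conv_channels):
        kernel, pad, stride = spec.layer_geometry(i)
        layers.append(nn.Conv3d(cin, int(cout), kernel, stride, pad, rng=rng))
        layers.append(nn.InstanceNorm3d())
        layers.append(nn.ReLU())
        cin = int(cout)
    _, flatten_len = output_shape(spec, input_shape)
    layers.append(nn.Flatten())
    f1, f2 = (int(v) for v in spec.fc_sizes)
    layers.append(nn.Linear(flatten_len, f1, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Linear(f1, f2, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Linear(f2, int(n_classes), rng=rng))
    return Network(layers)


def _as_batch(X) -> np.ndarray:
    """Coerce input to a float array of shape (N, 1, H, W, T)."""
    if hasattr(X, "values") and not isinstance(X, np.ndarray):  # SignalTensor
        X = [X]
    if isinstance(X, (list, tuple)) and X and hasattr(X[0], "values"):
        X = np.stack([np.asarray(t.values, dtype=float) for t in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 4:  # (N, H, W, T) -> add channel axis
        X = X[:, None]
    if X.ndim != 5:
        raise ValueError(f"expected (N, 1, H, W, T) input, got shape {X.shape}")
    return X


class Conv3DWordClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the numpy 3D CNN.

    Parameters
    ----------
    conv_channels, fc_sizes, axis_order : see :class:`ConvSpec`.
    learning_rate, batch_size, epochs : Adam training hyperparameters.
    random_state : seed controlling init and batch shuffling; a fixed seed
        gives a bit-identical training log across runs on one machine.

    Fitted attributes
    -----------------
    classes_ : sorted class labels.
    model_ : the trained :class:`~strainspeech.nn.Network`.
    training_log_ : mean cross-entropy per epoch.
    input_shape_ : (H, W, T) accepted by ``predict``.
    """

    def __init__(self, conv_channels=(8, 16, 16, 32, 32, 64, 64),
                 fc_sizes=(256, 128), axis_order="hwt", learning_rate=1e-3,
                 batch_size=16, epochs=50, random_state=0):
        self.conv_channels = conv_channels
        self.fc_sizes = fc_sizes
        self.axis_order = axis_order
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _spec(self) -> ConvSpec:
        return ConvSpec(tuple(self.conv_channels), tuple(self.fc_sizes), self.axis_order)

    def fit(self, X, y) -> "Conv3DWordClassifier":
        X = _as_batch(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        cfg = TrainConfig(self.learning_rate, self.batch_size, self.epochs,
                          int(self.random_state))
        self.input_shape_ = X.shape[2:]
        self.model_ = build_model(self._spec(), self.classes_.size,
                                  self.input_shape_, seed=cfg.seed)
        self.training_log_ = self._run_epochs(self.model_.parameters(), X, y_enc, cfg)
        return self

    def _run_epochs(self, handles, X, y_enc, cfg: TrainConfig) -> list:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
        opt = nn.Adam(handles, lr=cfg.learning_rate)
        n = X.shape[0]
        log = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self.model_.forward(X[idx])
                loss, dlogits = nn.softmax_cross_entropy(logits, y_enc[idx])
                self.model_.backward(dlogits)
                opt.step()
                losses.append(loss * idx.size)
            log.append(float(np.sum(losses) / n))
        return log

    def _check_fitted_input(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        X = _as_batch(X)
        if X.shape[2:] != tuple(self.input_shape_):
            raise ValueError(
                f"input shape {X.shape[2:]} != training shape {tuple(self.input_shape_)}")
        return X

    def decision_function(self, X) -> np.ndarray:
        X = self._check_fitted_input(X)
        out = [self.model_.forward(X[i:i + 32]) for i in range(0, X.shape[0], 32)]
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        # np.argmax breaks ties toward the lowest index, hence lowest class
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def extract_features(self, X) -> np.ndarray:
        """Penultimate-FC activations (input of the classification layer)."""
        X = self._check_fitted_input(X)
        feats = []
        for i in range(0, X.shape[0], 32):
            outputs = self.model_.forward_collect(X[i:i + 32])
            feats.append(outputs[-2])
        return np.concatenate(feats)

    def fine_tune(self, X, y, epochs: int = 20,
                  learning_rate: Optional[float] = None,
                  trainable: str = "fc") -> "Conv3DWordClassifier":
        """Adapt the fitted model in place on new labelled data.

        ``trainable='fc'`` freezes every convolution layer and updates only
        the fully connected stack (the transfer-learning recipe for a new
        subject/sensor placement); ``'all'`` updates everything.
        """
        X = self._check_fitted_input(X)
        y = np.asarray(y)
        unknown = np.setdiff1d(np.unique(y), self.classes_)
        if unknown.size:
            raise ValueError(f"labels {unknown.tolist()} not in the training vocabulary")
        if epochs < 1:
            return self
        y_enc = np.searchsorted(self.classes_, y)
        lr = self.learning_rate / 10.0 if learning_rate is None else learning_rate
        if trainable == "fc":
            handles = [(layer, name) for layer, name in self.model_.parameters()
                       if isinstance(layer, nn.Linear)]
        elif trainable == "all":
            handles = self.model_.parameters()
        else:
            raise ValueError("trainable must be 'fc' or 'all'")
        cfg = TrainConfig(lr, self.batch_size, epochs, int(self.random_state) + 1)
        self.training_log_ = list(self.training_log_) + self._run_epochs(
            handles, X, y_enc, cfg)
        return self


class CorrelationWordClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-reference classifier under cosine similarity.

    ``fit`` stores the (flattened) reference recordings; each query gets the
    class of the most similar reference, ties broken toward the lowest class
    label. With one reference per class this is the template-matching
    baseline; with several it is 1-nearest-neighbour in cosine distance.
    """

    def fit(self, X, y) -> "CorrelationWordClassifier":
        X = _flatten_2d(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        order = np.argsort(y, kind="stable")  # lowest class first => argmax tie rule
        self.references_ = X[order]
        self.reference_labels_ = y[order]
        self.classes_ = np.unique(y)
        norms = np.linalg.norm(self.references_, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm reference vector")
        self._unit_refs = self.references_ / norms[:, None]
        return self

    def similarity(self, X) -> np.ndarray:
        X = _flatten_2d(X)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm query vector")
        return (X / norms[:, None]) @ self._unit_refs.T

    def predict(self, X) -> np.ndarray:
        sim = self.similarity(X)
        return self.reference_labels_[np.argmax(sim, axis=1)]


class SVMWordClassifier(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM baseline on flattened preprocessed tensors."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y) -> "SVMWordClassifier":
        X = _flatten_2d(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.svc_ = SVC(kernel="linear", C=self.C, decision_function_shape="ovr")
        self.svc_.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.svc_.predict(_flatten_2d(X))


def _flatten_2d(X) -> np.ndarray:
    if isinstance(X, (list, tuple)) and X and hasattr(X[0], "values"):
        X = np.stack([np.asarray(t.values, dtype=float) for t in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None]
    return X.reshape(X.shape[0], -1)


# ---------------------------------------------------------------------------
# thin functional wrappers


def train(X, y, spec: Optional[ConvSpec] = None,
          config: Optional[TrainConfig] = None) -> Conv3DWordClassifier:
    spec = spec if spec is not None else ConvSpec()
    cfg = config if config is not None else TrainConfig()
    clf = Conv3DWordClassifier(
        conv_channels=spec.conv_channels, fc_sizes=spec.fc_sizes,
        axis_order=spec.axis_order, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, epochs=cfg.epochs, random_state=cfg.seed)
    return clf.fit(X, y)


def predict(model: Conv3DWordClassifier, X) -> tuple:
    """(probability matrix, argmax labels)."""
    proba = model.predict_proba(X)
    return proba, model.classes_[np.argmax(proba, axis=1)]


def extract_features(model: Conv3DWordClassifier, X) -> np.ndarray:
    return model.extract_features(X)


def correlation_classify(references, reference_labels, queries) -> np.ndarray:
    """Template-matching prediction; references must cover every class once."""
    labels = np.asarray(reference_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts != 1):
        raise ValueError("references must contain every class exactly once")
    clf = CorrelationWordClassifier().fit(references, labels)
    return clf.predict(queries)


def correlation_cv(X, y, groups) -> tuple:
    """Rotate each repetition group in as the reference set.

    ``groups[i]`` identifies the reference dataset (one repetition of every
    word) record ``i`` belongs to. Each group in turn serves as the
    reference; all remaining records are classified and the per-group
    accuracies are averaged arithmetically.

    Returns (per-group accuracies, mean accuracy), accuracies in [0, 1].
    """
    X = _flatten_2d(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    uniq_groups = np.unique(groups)
    if uniq_groups.size < 2:
        raise ValueError("need at least 2 reference groups")
    all_classes = np.unique(y)
    accs = []
    for g in uniq_groups:
        ref_mask = groups == g
        missing = np.setdiff1d(all_classes, np.unique(y[ref_mask]))
        if missing.size:
            raise ValueError(f"reference group {g} is missing classes {missing.tolist()}")
        pred = correlation_classify(X[ref_mask], y[ref_mask], X[~ref_mask])
        accs.append(float(np.mean(pred == y[~ref_mask])))
    return accs, float(np.mean(accs))


def svm_classify(X_train, y_train, X_test, C: float = 1.0) -> np.ndarray:
    return SVMWordClassifier(C=C).fit(X_train, y_train).predict(X_test)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: Conv3DWordClassifier, path) -> None:
    """Single-file .npz checkpoint: parameters + architecture + vocabulary."""
    if not hasattr(model, "model_"):
        raise RuntimeError("cannot checkpoint an unfitted classifier")
    meta = {
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "input_shape": [int(v) for v in model.input_shape_],
        "training_log": [float(v) for v in model.training_log_],
    }
    arrays = model.model_.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Conv3DWordClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    clf = Conv3DWordClassifier(**{k: v for k, v in meta["params"].items()})
    clf.classes_ = np.asarray(meta["classes"])
    clf.input_shape_ = tuple(meta["input_shape"])
    clf.training_log_ = meta["training_log"]
    clf.model_ = build_model(clf._spec(), clf.classes_.size, clf.input_shape_,
                             seed=int(clf.random_state))
    clf.model_.load_state_arrays(arrays)
    return clf
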