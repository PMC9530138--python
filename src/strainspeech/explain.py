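"""Model introspection: relevance-weighted class activation maps (R-CAM),
t-SNE feature embedding and cluster-quality scoring.

R-CAM attributes a classification decision to regions of the input strain
tensor: the target-class score is propagated back to a chosen convolution
layer with epsilon-rule layer-wise relevance propagation (LRP), each feature
channel of that layer is weighted by its total relevance, and the positive
part of the weighted activation sum is upsampled along time and min–max
normalized to [0, 1]. A gradient-weighted (Grad-CAM-style) channel weighting
is available as an alternative via ``method='grad'``.

Epsilon-LRP rules used here: linear and convolution layers redistribute
relevance as R_in = x * W^T (R_out / (z + eps*sign(z))); ReLU and instance
normalization pass relevance through unchanged; flatten reshapes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from . import nn
from .classify import Conv3DWordClassifier, N_CONV_LAYERS
from .preprocess import DEFAULT_CHANNEL_MAP, H, W

__all__ = [
    "RelevanceMap",
    "rcam",
    "localization_score",
    "tsne_embed",
    "silhouette",
]

_LRP_EPS = 1e-6


@dataclass
class RelevanceMap:
    """Attribution map aligned to the input tensor, values in [0, 1]."""

    values: np.ndarray  # (H, W, T)
    target_class: int
    layer: int
    method: str = "lrp"
    duration: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[:2] != (H, W):
            raise ValueError(f"values must have shape ({H}, {W}, T)")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise ValueError("map values must lie in [0, 1]")
        self.values = v


def _sign(z: np.ndarray) -> np.ndarray:
    s = np.sign(z)
    s[s == 0] = 1.0
    return s


def _lrp_backward(network: nn.Network, inputs: list, relevance: np.ndarray,
                  stop_at: int) -> np.ndarray:
    """Propagate relevance from the output down to the output of layer
    ``stop_at`` (i.e. through layers stop_at+1 .. end)."""
    for i in range(len(network.layers) - 1, stop_at, -1):
        layer = network.layers[i]
        x = inputs[i]
        if isinstance(layer, nn.Linear):
            z = x @ layer.params["W"].T + layer.params["b"]
            s = relevance / (z + _LRP_EPS * _sign(z))
            relevance = x * (s @ layer.params["W"])
        elif isinstance(layer, nn.Conv3d):
            z = layer.forward(x)
            s = relevance / (z + _LRP_EPS * _sign(z))
            relevance = x * layer.input_grad(s, x.shape)
        elif isinstance(layer, nn.Flatten):
            relevance = relevance.reshape(x.shape)
        else:  # ReLU, InstanceNorm3d: identity pass
            pass
    return relevance


def rcam(model: Conv3DWordClassifier, X, target_class: int,
         layer: int = 7, method: str = "lrp",
         weighting: str = "elementwise") -> RelevanceMap:
    """Relevance-weighted class activation map for one input.

    Parameters
    ----------
    model : fitted CNN classifier.
    X : one input tensor, shape (1, 2, 4, T), (1, 1, 2, 4, T) or a
        SignalTensor.
    target_class : class label whose evidence is mapped.
    layer : source convolution layer, 1..7; its feature maps are weighted.
        The last conv layer is the default: its receptive fields carry class
        evidence while still resolving half the input frames.
    method : 'lrp' (epsilon-rule relevance weights) or 'grad'
        (gradient-weighted channel importance, Grad-CAM style).
    weighting : for 'lrp', how relevance weights the activation maps:
        'elementwise' (default) multiplies each activation by its own
        relevance before summing channels, preserving spatial localization;
        'channel' collapses relevance to one weight per feature channel
        first. 'grad' always uses per-channel weights.
    """
    if not hasattr(model, "model_"):
        raise RuntimeError("model is not fitted")
    if not 1 <= layer <= N_CONV_LAYERS:
        raise ValueError(f"layer must be in 1..{N_CONV_LAYERS}")
    if method not in ("lrp", "grad"):
        raise ValueError("method must be 'lrp' or 'grad'")
    if weighting not in ("elementwise", "channel"):
        raise ValueError("weighting must be 'elementwise' or 'channel'")
    cls_idx = np.flatnonzero(model.classes_ == target_class)
    if cls_idx.size == 0:
        raise ValueError(f"unknown class {target_class!r}")
    cls_idx = int(cls_idx[0])

    x = model._check_fitted_input(X)
    if x.shape[0] != 1:
        raise ValueError("rcam maps one record at a time")
    net = model.model_
    outputs = net.forward_collect(x)
    inputs = [x] + outputs[:-1]
    act_index = 3 * (layer - 1) + 2  # post-ReLU output of the conv block
    activations = outputs[act_index][0]  # (C, H', W', T')

    logits = outputs[-1]
    if method == "lrp":
        relevance = np.zeros_like(logits)
        relevance[0, cls_idx] = logits[0, cls_idx]
        rel = _lrp_backward(net, inputs, relevance, act_index)[0]
        if weighting == "elementwise":
            cam = np.maximum((rel * activations).sum(axis=0), 0.0)
        else:
            weights = rel.sum(axis=(1, 2, 3))
            cam = np.maximum(np.tensordot(weights, activations, axes=1), 0.0)
    else:
        dlogits = np.zeros_like(logits)
        dlogits[0, cls_idx] = 1.0
        grad = net.backward(dlogits, upto=act_index + 1)[0]
        weights = grad.mean(axis=(1, 2, 3))
        cam = np.maximum(np.tensordot(weights, activations, axes=1), 0.0)  # (H', W', T')
    t_in = x.shape[4]
    full = np.zeros((H, W, t_in))
    h_src, w_src, t_src = cam.shape
    src_t = np.arange(t_src) * (t_in / t_src)
    dst_t = np.arange(t_in)
    for i in range(H):
        si = min(i * h_src // H, h_src - 1) if h_src < H else i
        for j in range(W):
            sj = min(j * w_src // W, w_src - 1) if w_src < W else j
            full[i, j] = np.interp(dst_t, src_t, cam[si, sj])
    peak = full.max()
    if peak > 0:
        full = full / peak
    tag = method if method == "grad" else f"{method}-{weighting}"
    return RelevanceMap(full, int(target_class), int(layer), tag)


def localization_score(rmap: RelevanceMap, window: tuple,
                       channels: Optional[Sequence[int]] = None,
                       channel_map: Optional[dict] = None) -> float:
    """Fraction of total relevance mass inside a time window and channel set."""
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    total = rmap.values.sum()
    if total == 0:
        raise ValueError("all-zero relevance map")
    t_len = rmap.values.shape[2]
    times = (np.arange(t_len) + 0.5) * (rmap.duration / t_len)
    t_mask = (times >= t0) & (times <= t1)
    cmap = dict(DEFAULT_CHANNEL_MAP) if channel_map is None else dict(channel_map)
    if channels is None:
        cell_mask = np.ones((H, W), dtype=bool)
    else:
        wanted = set(int(c) for c in channels)
        cell_mask = np.zeros((H, W), dtype=bool)
        for (row, col), ch in cmap.items():
            if ch in wanted:
                cell_mask[row, col] = True
    inside = rmap.values[cell_mask][:, t_mask].sum()
    return float(inside / total)


def tsne_embed(features, dims: int = 2, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D/3-D t-SNE embedding of feature vectors (delegates to sklearn)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array (n_points, n_dims)")
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least 3*perplexity={3 * perplexity:.0f} points, got {X.shape[0]}")
    tsne = TSNE(n_components=dims, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(X)


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient in [-1, 1].

    Uses the standard convention s(i) = 0 for singleton clusters; when every
    cluster is a singleton the mean is therefore 0.
    """
    X = np.asarray(points, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("silhouette requires at least 2 classes")
    if classes.size == y.size:  # every cluster a singleton: s(i) = 0 for all i
        return 0.0
    return float(silhouette_score(X, y))
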