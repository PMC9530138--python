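"""Evaluation protocols: cross-validation, learning curves, channel
ablation, confusion matrices, transfer adaptation and SNR.

All protocols operate on a preprocessed tensor array ``X`` of shape
(N, 1, 2, 4, T) with integer labels ``y`` and take a *pipeline factory* — a
zero-argument callable returning a fresh unfitted classifier — so the same
harness evaluates the CNN and both baselines. Splits are stratified by
class (at desk scale an unstratified shuffle can drop a class from a fold
entirely) and every source of randomness is an explicit seed, so a report
is a pure function of (data, factory, seed).
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .preprocess import DEFAULT_CHANNEL_MAP

__all__ = [
    "EvalReport",
    "kfold_split",
    "cross_validate",
    "learning_curve",
    "channel_ablation",
    "confusion_matrix",
    "transfer_adapt",
    "snr",
]


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold accuracies (%), their arithmetic
    mean, and the pooled confusion matrix over all test folds."""

    fold_accuracies: list
    mean_accuracy: float
    confusion: list
    n_records: int
    seed: int
    experiment: str = "cross_validation"
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def kfold_split(y, k: int = 5, seed: int = 0) -> list:
    """Seeded stratified partition into k folds of test indices.

    Folds are disjoint, cover every record, and differ in size by at most
    one per class.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > y.size:
        raise ValueError(f"k={k} exceeds dataset size {y.size}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k records for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(y.size), y)]


def _accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def cross_validate(factory: Callable, X, y, k: int = 5, seed: int = 0,
                   config: Optional[dict] = None) -> EvalReport:
    """k-fold cross-validation: train on k-1 folds, test on the held-out one.

    Reports the per-fold accuracies and their arithmetic mean (not the
    pooled accuracy — they differ when folds are unequal) plus the pooled
    confusion matrix; every record is tested exactly once.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    folds = kfold_split(y, k=k, seed=seed)
    classes = np.unique(y)
    n_classes = classes.size
    label_of = {c: i for i, c in enumerate(classes)}
    accs = []
    pooled = np.zeros((n_classes, n_classes), dtype=int)
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        clf = factory()
        clf.fit(X[train_mask], y[train_mask])
        pred = clf.predict(X[test_idx])
        accs.append(100.0 * _accuracy(y[test_idx], pred))
        ti = np.array([label_of[v] for v in y[test_idx]])
        pi = np.array([label_of[v] for v in pred])
        pooled += confusion_matrix(ti, pi, n_classes)
    return EvalReport(
        fold_accuracies=[float(a) for a in accs],
        mean_accuracy=float(np.mean(accs)),
        confusion=pooled.tolist(),
        n_records=int(y.size),
        seed=int(seed),
        config=dict(config or {}),
    )


def learning_curve(factory: Callable, X, y, sizes: Sequence[int],
                   repeats: int = 5, k: int = 5, seed: int = 0) -> dict:
    """Accuracy versus training-set size with a fixed test fold.

    The last of the k folds is held fixed as the test set; for each
    requested size ``n``, ``repeats`` stratified subsets of n records are
    drawn from the remaining pool, a fresh model is trained on each and
    evaluated on the fixed fold. Returns per-size mean accuracy (%).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    X = np.asarray(X)
    y = np.asarray(y)
    folds = kfold_split(y, k=k, seed=seed)
    test_idx = folds[-1]
    pool = np.setdiff1d(np.arange(y.size), test_idx)
    if max(sizes) > pool.size:
        raise ValueError(f"requested size {max(sizes)} exceeds pool {pool.size}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1C]))
    means, raw = [], []
    for n in sizes:
        accs = []
        for _ in range(repeats):
            idx = _stratified_sample(y, pool, n, rng)
            clf = factory()
            clf.fit(X[idx], y[idx])
            accs.append(100.0 * _accuracy(y[test_idx], clf.predict(X[test_idx])))
        means.append(float(np.mean(accs)))
        raw.append([float(a) for a in accs])
    return {"sizes": sizes, "mean_accuracy": means, "accuracies": raw,
            "test_fold_size": int(test_idx.size), "seed": int(seed)}


def _stratified_sample(y, pool, n, rng) -> np.ndarray:
    """n records from pool, class proportions as even as possible."""
    y_pool = y[pool]
    classes = np.unique(y_pool)
    per, extra = divmod(n, classes.size)
    counts = {c: per for c in classes}
    for c in rng.permutation(classes)[:extra]:
        counts[c] += 1
    chosen = []
    for c in classes:
        members = pool[y_pool == c]
        take = min(counts[c], members.size)
        chosen.append(rng.choice(members, size=take, replace=False))
    idx = np.concatenate(chosen)
    if idx.size < n:  # top up from the leftovers if a class ran short
        rest = np.setdiff1d(pool, idx)
        idx = np.concatenate([idx, rng.choice(rest, size=n - idx.size, replace=False)])
    return np.sort(idx)


def mask_channels(X, keep: Sequence[int], channel_map: Optional[dict] = None) -> np.ndarray:
    """Zero every tensor cell whose channel id is not in ``keep``."""
    cmap = dict(DEFAULT_CHANNEL_MAP) if channel_map is None else dict(channel_map)
    Xm = np.array(X, dtype=float, copy=True)
    keep = set(int(c) for c in keep)
    for (row, col), ch in cmap.items():
        if ch not in keep:
            Xm[:, :, row, col, :] = 0.0
    return Xm


def channel_ablation(factory: Callable, X, y, n_channels: int, seed: int = 0,
                     subsets: Optional[Sequence[Sequence[int]]] = None,
                     mode: str = "retrain", test_fraction: float = 0.25,
                     channel_map: Optional[dict] = None) -> dict:
    """Mean accuracy over channel subsets of size ``n_channels``.

    By default every one of the C(8, n) subsets is evaluated: the
    complementary channels are zero-masked, the model is retrained on a
    fixed stratified split and tested on its held-out part
    (``mode='retrain'``). ``mode='mask_only'`` trains once on the full
    8-channel data and only masks at test time (cheap screening variant).
    ``subsets`` restricts evaluation to an explicit list of subsets.
    """
    if not 1 <= n_channels <= 8:
        raise ValueError("n_channels must be in 1..8")
    if mode not in ("retrain", "mask_only"):
        raise ValueError("mode must be 'retrain' or 'mask_only'")
    X = np.asarray(X)
    y = np.asarray(y)
    if subsets is None:
        subsets = list(itertools.combinations(range(8), n_channels))
    else:
        subsets = [tuple(sorted(int(c) for c in s)) for s in subsets]
        if len(set(subsets)) != len(subsets):
            raise ValueError("duplicate channel subsets")
        if any(len(s) != n_channels for s in subsets):
            raise ValueError("every subset must have n_channels channels")
    k = max(2, int(round(1.0 / test_fraction)))
    test_idx = kfold_split(y, k=k, seed=seed)[0]
    train_mask = np.ones(y.size, dtype=bool)
    train_mask[test_idx] = False

    full_model = None
    if mode == "mask_only":
        full_model = factory()
        full_model.fit(X[train_mask], y[train_mask])

    per_subset = {}
    for subset in subsets:
        Xm = mask_channels(X, subset, channel_map)
        if mode == "retrain":
            clf = factory()
            clf.fit(Xm[train_mask], y[train_mask])
        else:
            clf = full_model
        pred = clf.predict(Xm[test_idx])
        per_subset[subset] = 100.0 * _accuracy(y[test_idx], pred)
    return {
        "n_channels": n_channels,
        "subset_accuracies": per_subset,
        "mean_accuracy": float(np.mean(list(per_subset.values()))),
        "n_subsets": len(per_subset),
        "mode": mode,
        "seed": int(seed),
    }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts matrix, entry (i, j) = records of true class i predicted j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def transfer_adapt(model, X_adapt, y_adapt, X_test, y_test,
                   sizes_per_class: Sequence[int] = (0, 5, 10, 20),
                   epochs: int = 20, learning_rate: Optional[float] = None,
                   seed: int = 0) -> dict:
    """Few-shot adaptation of a fitted CNN to a shifted domain.

    For each adaptation budget ``n`` (records per class; 0 = no adaptation)
    a copy of the model has its convolution layers frozen and its FC stack
    fine-tuned on n examples per class from the shifted domain, then is
    scored on held-out shifted-domain data. Returns the accuracy curve and
    the model adapted with the largest budget.
    """
    y_adapt = np.asarray(y_adapt)
    y_test = np.asarray(y_test)
    X_adapt = np.asarray(X_adapt)
    X_test = np.asarray(X_test)
    unknown = np.setdiff1d(np.unique(y_adapt), model.classes_)
    if unknown.size:
        raise ValueError(f"adaptation labels {unknown.tolist()} not in model vocabulary")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xADA]))
    curve = []
    adapted = None
    for n in sizes_per_class:
        if n == 0:
            clf = model
        else:
            idx = []
            for c in np.unique(y_adapt):
                members = np.flatnonzero(y_adapt == c)
                if members.size < n:
                    raise ValueError(f"class {c} has fewer than {n} adaptation records")
                idx.append(rng.choice(members, size=n, replace=False))
            idx = np.concatenate(idx)
            clf = copy.deepcopy(model)
            clf.fine_tune(X_adapt[idx], y_adapt[idx], epochs=epochs,
                          learning_rate=learning_rate, trainable="fc")
            adapted = clf
        curve.append(100.0 * _accuracy(y_test, clf.predict(X_test)))
    return {
        "sizes_per_class": list(sizes_per_class),
        "accuracy": [float(a) for a in curve],
        "seed": int(seed),
        "adapted_model": adapted,
    }


def snr(active_segment, rest_segment) -> float:
    """Signal-to-noise ratio as RMS(active) / RMS(rest)."""
    a = np.asarray(active_segment, dtype=float).ravel()
    r = np.asarray(rest_segment, dtype=float).ravel()
    if a.size == 0 or r.size == 0:
        raise ValueError("segments must be non-empty")
    rms_rest = float(np.sqrt(np.mean(r ** 2)))
    if rms_rest == 0:
        raise ValueError("rest segment has zero RMS")
    return float(np.sqrt(np.mean(a ** 2)) / rms_rest)
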