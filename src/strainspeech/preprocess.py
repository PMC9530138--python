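"""Raw-trace conditioning and 2x4xT input-tensor assembly.

Each 8-channel utterance is turned into the classifier input
``X in R^{1 x H x W x T}`` with H=2 (horizontal/vertical gauge axis) and
W=4 (sensor sites S1..S4): per channel the trace is min–max normalized to
[0, 1], denoised with a Savitzky–Golay filter and resampled onto a fixed
uniform grid, then the 8 conditioned traces are laid out on the 2x4 spatial
grid so that adjacent sites sit in adjacent tensor columns.

The default stage order is normalize -> smooth -> regrid; smoothing a
[0, 1]-normalized trace can overshoot the range slightly at sharp features,
so the result is clipped back to [0, 1] (the clipped mass is reported via
``logging`` at DEBUG level). The alternative smooth-first order, which makes
clipping a no-op, is available via ``normalize_first=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import StrainRecord, N_CHANNELS

__all__ = [
    "PreprocessConfig",
    "SignalTensor",
    "SignalPreprocessor",
    "minmax_normalize",
    "savgol_smooth",
    "to_fixed_grid",
    "assemble_tensor",
    "preprocess_record",
    "DEFAULT_CHANNEL_MAP",
]

logger = logging.getLogger(__name__)

H, W = 2, 4

#: (row, col) -> 0-based channel index. Row 0 = horizontal gauges of sites
#: S1..S4 left to right, row 1 = vertical gauges in the same site order.
DEFAULT_CHANNEL_MAP: dict = {(0, s): 2 * s for s in range(W)} | {(1, s): 2 * s + 1 for s in range(W)}


@dataclass(frozen=True)
class PreprocessConfig:
    savgol_window: int = 15  # samples; 50 ms at 300 Hz
    savgol_polyorder: int = 3
    normalize_first: bool = True
    out_len: int = 600
    out_duration: float = 2.0
    in_rate: float = 300.0

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window < 1:
            raise ValueError("savgol_window must be a positive odd integer")
        if self.savgol_polyorder >= self.savgol_window:
            raise ValueError("savgol_polyorder must be < savgol_window")
        if self.out_len < 2:
            raise ValueError("out_len must be >= 2")
        if self.out_duration <= 0 or self.in_rate <= 0:
            raise ValueError("out_duration and in_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


@dataclass
class SignalTensor:
    """Preprocessed model input of shape (1, 2, 4, T)."""

    values: np.ndarray
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    label: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[:3] != (1, H, W) or v.shape[3] < 1:
            raise ValueError(f"values must have shape (1, {H}, {W}, T), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def channels(self) -> np.ndarray:
        """Invert the placement: the 8 traces in channel order, shape (8, T)."""
        out = np.empty((N_CHANNELS, self.n_frames))
        for (row, col), ch in self.channel_map.items():
            out[ch] = self.values[0, row, col]
        return out


def minmax_normalize(trace) -> np.ndarray:
    """Map a trace affinely onto [0, 1]; constant traces map to all zeros."""
    x = np.asarray(trace, dtype=float)
    if x.size < 1:
        raise ValueError("trace must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains NaN or inf")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.debug("constant trace normalized to zeros (degenerate record)")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def savgol_smooth(trace, window: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay smoothing with mirror-padded edges.

    Each sample is replaced by the centre value of the least-squares
    polynomial of degree ``polyorder`` fitted over its ``window``-sample
    neighbourhood; a polynomial of degree <= polyorder is reproduced exactly
    at interior points.
    """
    x = np.asarray(trace, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if x.size < window:
        raise ValueError("trace shorter than the filter window")
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="mirror")


def to_fixed_grid(trace, in_rate: float, out_len: int, out_duration: float) -> np.ndarray:
    """Linear-interpolation resampling onto ``out_len`` uniform samples.

    Both grids start at t=0 with spacing 1/rate, so an input already on the
    target grid is returned unchanged (up to float identity).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if in_rate <= 0 or out_len < 2 or out_duration <= 0:
        raise ValueError("in_rate, out_len and out_duration must be positive (out_len >= 2)")
    out_rate = out_len / out_duration
    if out_rate == in_rate and x.size == out_len:  # already on the target grid
        return x.copy()
    t_in = np.arange(x.size) / in_rate
    t_out = np.arange(out_len) / out_rate
    return np.interp(t_out, t_in, x)


def assemble_tensor(channels, channel_map: Optional[dict] = None,
                    label: Optional[int] = None) -> SignalTensor:
    """Lay the 8 conditioned traces out on the 2x4 (axis x site) grid."""
    arr = np.asarray(channels, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} equal-length channels, got shape {arr.shape}")
    cmap = dict(DEFAULT_CHANNEL_MAP) if channel_map is None else dict(channel_map)
    values = np.empty((1, H, W, arr.shape[1]))
    for (row, col), ch in cmap.items():
        values[0, row, col] = arr[ch]
    return SignalTensor(values, cmap, label)


def preprocess_record(record: StrainRecord,
                      config: Optional[PreprocessConfig] = None) -> SignalTensor:
    """Full per-channel pipeline producing the (1, 2, 4, T) model input."""
    cfg = config if config is not None else PreprocessConfig()
    out = np.empty((N_CHANNELS, cfg.out_len))
    clipped = 0.0
    for c in range(N_CHANNELS):
        x = record.waveform[c]
        if cfg.normalize_first:
            x = minmax_normalize(x)
            x = savgol_smooth(x, cfg.savgol_window, cfg.savgol_polyorder)
            over = np.clip(x - 1.0, 0.0, None).sum() + np.clip(-x, 0.0, None).sum()
            clipped += float(over)
            x = np.clip(x, 0.0, 1.0)
        else:
            x = savgol_smooth(x, cfg.savgol_window, cfg.savgol_polyorder)
            x = minmax_normalize(x)
        out[c] = to_fixed_grid(x, cfg.in_rate, cfg.out_len, cfg.out_duration)
    if clipped > 0:
        logger.debug("post-smoothing clip to [0,1]: total clipped mass %.3g", clipped)
    return assemble_tensor(out, label=record.class_id)


class SignalPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: list of StrainRecord -> (N, 1, 2, 4, T).

    Parameters mirror :class:`PreprocessConfig`; ``fit`` only validates and
    the transform is deterministic, so the transformer composes with sklearn
    pipelines and cross-validation without leakage concerns.
    """

    def __init__(self, savgol_window: int = 15, savgol_polyorder: int = 3,
                 normalize_first: bool = True, out_len: int = 600,
                 out_duration: float = 2.0, in_rate: float = 300.0):
        self.savgol_window = savgol_window
        self.savgol_polyorder = savgol_polyorder
        self.normalize_first = normalize_first
        self.out_len = out_len
        self.out_duration = out_duration
        self.in_rate = in_rate

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(self.savgol_window, self.savgol_polyorder,
                                self.normalize_first, self.out_len,
                                self.out_duration, self.in_rate)

    def fit(self, X: Sequence[StrainRecord], y=None) -> "SignalPreprocessor":
        self._config()  # validate parameters
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else 0
        return self

    def transform(self, X: Sequence[StrainRecord]) -> np.ndarray:
        cfg = self._config()
        return np.stack([preprocess_record(r, cfg).values for r in X])

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y).transform(X)
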