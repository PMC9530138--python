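"""Synthetic 8-channel strain-recording generator.

Emulates the structure of a word-utterance dataset recorded by four biaxial
strain-gauge sites around the mouth (4 sites x 2 orthogonal gauges = 8
channels, 300 samples/s, 2 s per utterance). Each word class is defined by a
:class:`WordTemplate` — a sum of Gaussian articulation bumps per channel —
and each repetition perturbs the template with utterance-level timing jitter,
amplitude jitter, slow baseline drift and white sensor noise. The two gauges
of one site share bump centres: orthogonal gauges glued to one patch of skin
deform simultaneously, so their activity is time-locked.

Channel convention used throughout the package (0-based indices):
``0,2,4,6`` are the horizontal gauges of sites S1..S4 and ``1,3,5,7`` the
vertical gauges of the same sites, i.e. channel ``2*s`` / ``2*s+1`` is the
horizontal / vertical gauge of site ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "WordTemplate",
    "StrainRecord",
    "make_templates",
    "synth_record",
    "synth_dataset",
    "plant_discriminative_window",
]

N_CHANNELS = 8
N_SITES = 4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic recordings.

    Defaults mirror the recording protocol the simulator emulates: 100-word
    vocabulary, 100 repetitions per word pooled over two subjects, sampled at
    300 Hz for 2 s. Jitter/noise magnitudes are chosen to produce visibly
    repeatable but not identical repetitions (bump amplitudes are O(1) in
    dR/R units, so ``noise_sd=0.02`` is a high-SNR sensor).
    """

    n_classes: int = 100
    reps_per_class: int = 50
    n_subjects: int = 2
    sampling_rate: float = 300.0
    duration: float = 2.0
    n_bumps: int = 3
    noise_sd: float = 0.02
    time_jitter_sd: float = 0.05
    amp_jitter_sd: float = 0.10
    drift_amplitude: float = 0.05
    subject_amp_sd: float = 0.10
    subject_time_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.reps_per_class < 1 or self.n_subjects < 1:
            raise ValueError("reps_per_class and n_subjects must be >= 1")
        n = self.sampling_rate * self.duration
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("sampling_rate * duration must be an integer >= 2")
        for name in ("noise_sd", "time_jitter_sd", "amp_jitter_sd",
                     "drift_amplitude", "subject_amp_sd", "subject_time_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_bumps < 1:
            raise ValueError("n_bumps must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class WordTemplate:
    """Noiseless per-class waveform parameters: K Gaussian bumps per channel.

    ``centers``, ``widths``, ``amps`` are (8, K) arrays (seconds, seconds,
    dR/R units). Paired channels (2s, 2s+1) share ``centers`` rows.

    ``window``/``window_channels``/``windowed`` support planted-window
    fixtures: bumps flagged in the boolean (8, K) ``windowed`` mask are
    hard-masked to the time window on the listed channels, so outside the
    window all classes share the common part of the waveform exactly.
    """

    class_id: int
    centers: np.ndarray
    widths: np.ndarray
    amps: np.ndarray
    window: Optional[tuple] = None
    window_channels: Optional[tuple] = None
    windowed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("centers", "widths", "amps"):
            a = getattr(self, name)
            if a.shape[0] != N_CHANNELS or a.ndim != 2:
                raise ValueError(f"{name} must have shape (8, K)")
        if np.any(self.widths <= 0):
            raise ValueError("bump widths must be positive")
        for s in range(N_SITES):
            if not np.array_equal(self.centers[2 * s], self.centers[2 * s + 1]):
                raise ValueError("paired channels must share bump centers")

    @property
    def n_bumps(self) -> int:
        return self.centers.shape[1]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Noiseless waveform, shape (8, len(t))."""
        return _eval_bumps(self, t, time_shift=0.0, center_offsets=None, amp_factors=None)


@dataclass(frozen=True)
class StrainRecord:
    """One utterance: 8 aligned dR/R traces plus labels."""

    waveform: np.ndarray  # (8, T)
    class_id: int
    subject_id: int = 0
    session_id: int = 0
    rep_index: int = 0

    def __post_init__(self) -> None:
        if self.waveform.ndim != 2 or self.waveform.shape[0] != N_CHANNELS:
            raise ValueError("waveform must have shape (8, T)")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be finite")


def _eval_bumps(template: WordTemplate, t: np.ndarray, time_shift: float,
                center_offsets, amp_factors) -> np.ndarray:
    """Sum-of-Gaussians evaluation with optional per-channel perturbations."""
    out = np.zeros((N_CHANNELS, t.size))
    centers = template.centers
    if center_offsets is not None:
        centers = centers + center_offsets
    amps = template.amps if amp_factors is None else template.amps * amp_factors
    win_mask = None
    if template.window is not None:
        t0, t1 = template.window
        win_mask = (t >= t0) & (t <= t1)
    for c in range(N_CHANNELS):
        for k in range(template.n_bumps):
            bump = amps[c, k] * np.exp(
                -((t - centers[c, k] - time_shift) ** 2) / (2.0 * template.widths[c, k] ** 2)
            )
            if (win_mask is not None and template.windowed is not None
                    and template.windowed[c, k]):
                bump = bump * win_mask
            out[c] += bump
    return out


def _template_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11CE]))


def make_templates(config: SimConfig) -> list[WordTemplate]:
    """Draw ``n_classes`` word templates reproducibly from the config seed.

    Bump centres are uniform over the middle of the utterance window, widths
    80–250 ms (articulation-gesture scale), amplitudes in [-1.2, -0.3] or
    [0.3, 1.2] dR/R (both compressive and tensile skin strain occur).
    Paired channels share centres; widths and amplitudes differ per gauge.
    """
    rng = _template_rng(config)
    templates = []
    for cid in range(config.n_classes):
        centers = np.empty((N_CHANNELS, config.n_bumps))
        widths = np.empty((N_CHANNELS, config.n_bumps))
        amps = np.empty((N_CHANNELS, config.n_bumps))
        for s in range(N_SITES):
            mu = rng.uniform(0.1 * config.duration, 0.9 * config.duration, config.n_bumps)
            centers[2 * s] = mu
            centers[2 * s + 1] = mu
            for row in (2 * s, 2 * s + 1):
                widths[row] = rng.uniform(0.08, 0.25, config.n_bumps)
                sign = rng.choice([-1.0, 1.0], config.n_bumps)
                amps[row] = sign * rng.uniform(0.3, 1.2, config.n_bumps)
        templates.append(WordTemplate(cid, centers, widths, amps))
    return templates


def time_axis(config: SimConfig) -> np.ndarray:
    return np.arange(config.n_samples) / config.sampling_rate


def synth_record(template: WordTemplate, config: SimConfig,
                 rng: np.random.Generator, *, subject_id: int = 0,
                 session_id: int = 0, rep_index: int = 0,
                 center_offsets=None, amp_factors=None) -> StrainRecord:
    """Draw one noisy repetition of a template.

    waveform_c(t) = (1+A) * sum_k a_ck exp(-(t - mu_ck - D)^2 / (2 s_ck^2))
                    + drift(t) + noise(t)

    with one utterance-level timing shift D ~ N(0, time_jitter_sd) shared by
    all channels (articulation moves the whole face at once), amplitude
    jitter A ~ N(0, amp_jitter_sd), a slow random sinusoidal baseline drift
    bounded by ``drift_amplitude`` and white Gaussian sensor noise.
    """
    t = time_axis(config)
    delta = rng.normal(0.0, config.time_jitter_sd) if config.time_jitter_sd > 0 else 0.0
    amp_jit = rng.normal(0.0, config.amp_jitter_sd) if config.amp_jitter_sd > 0 else 0.0
    signal = (1.0 + amp_jit) * _eval_bumps(template, t, delta, center_offsets, amp_factors)
    if config.drift_amplitude > 0:
        for c in range(N_CHANNELS):
            a = rng.uniform(0.0, config.drift_amplitude)
            f = rng.uniform(0.1, 0.5)  # Hz, well below articulation bandwidth
            phi = rng.uniform(0.0, 2.0 * np.pi)
            signal[c] += a * np.sin(2.0 * np.pi * f * t + phi)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, signal.shape)
    return StrainRecord(signal, template.class_id, subject_id, session_id, rep_index)


def _subject_perturbations(config: SimConfig) -> list[tuple]:
    """Per-subject template perturbations (amplitude factor + centre offset).

    Subject 0 is the reference subject (no perturbation); further subjects
    get independent per-channel multiplicative amplitude factors and small
    centre offsets, mimicking sensor-placement and user dependency.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5AB1]))
    perturbations = [(None, None)]
    for _ in range(1, config.n_subjects):
        amp = rng.normal(1.0, config.subject_amp_sd, (N_CHANNELS, 1))
        off = rng.normal(0.0, config.subject_time_sd, (N_SITES, 1))
        off = np.repeat(off, 2, axis=0)  # paired channels keep shared centers
        perturbations.append((off, amp))
    return perturbations


def synth_dataset(config: SimConfig,
                  templates: Optional[Sequence[WordTemplate]] = None) -> list[StrainRecord]:
    """Generate the full balanced dataset.

    ``n_classes * reps_per_class * n_subjects`` records, fully determined by
    ``config.seed``; each record is drawn from a child RNG stream keyed by
    its (subject, class, rep) index so records are reproducible independent
    of generation order.
    """
    if templates is None:
        templates = make_templates(config)
    elif len(templates) != config.n_classes:
        raise ValueError("templates length must equal n_classes")
    perturbs = _subject_perturbations(config)
    records = []
    for subj in range(config.n_subjects):
        off, amp = perturbs[subj]
        for template in templates:
            for rep in range(config.reps_per_class):
                key = ((subj * config.n_classes) + template.class_id) * config.reps_per_class + rep
                rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDA7A, key]))
                records.append(
                    synth_record(template, config, rng, subject_id=subj,
                                 session_id=subj, rep_index=rep,
                                 center_offsets=off, amp_factors=amp)
                )
    return records


def perturb_templates(templates: Sequence[WordTemplate], seed: int,
                      width_scale: float = 1.6, center_offset_sd: float = 0.25,
                      amp_scale_sd: float = 0.0) -> list[WordTemplate]:
    """Domain-shifted copies of templates (sensor-misplacement emulation).

    Applies one per-site centre offset (shared by the paired channels, drawn
    once per template), a global bump-width scaling and optionally a
    per-channel amplitude rescaling. Used to synthesize an "unseen subject /
    re-attached sensor" domain for transfer-adaptation experiments: width
    and timing changes survive per-channel min–max normalization, so the
    shift is visible to the classifier.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F17]))
    out = []
    for t in templates:
        off = np.repeat(rng.normal(0.0, center_offset_sd, (N_SITES, 1)), 2, axis=0)
        amps = t.amps
        if amp_scale_sd > 0:
            amps = amps * rng.normal(1.0, amp_scale_sd, (N_CHANNELS, 1))
        out.append(WordTemplate(t.class_id, t.centers + off,
                                t.widths * width_scale, amps,
                                t.window, t.window_channels, t.windowed))
    return out


def plant_discriminative_window(config: SimConfig, window: tuple,
                                channels: Sequence[int]) -> list[WordTemplate]:
    """Templates whose class information lives only in a time window.

    All classes share one common waveform; class-specific bumps are confined
    (hard-masked) to ``window = (t0, t1)`` seconds on the given channels
    (0-based). Used to validate attribution maps and channel ablation: a
    correct explanation must concentrate inside the planted window, and a
    classifier must drop to chance when the window/channels are removed.
    """
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= config.duration):
        raise ValueError("window must satisfy 0 <= t0 < t1 <= duration")
    channels = tuple(sorted(set(int(c) for c in channels)))
    if not channels or any(c < 0 or c >= N_CHANNELS for c in channels):
        raise ValueError("channels must be a non-empty subset of 0..7")
    rng = _template_rng(config)
    K = config.n_bumps
    D = config.duration

    # The shared waveform is a pair of large "anchor" bumps (one positive,
    # one negative) placed as far from the window as possible. They pin each
    # channel's min and max, so the per-channel min-max normalization
    # constants are class-independent and no class information leaks outside
    # the window through the normalization.
    candidates = np.array([0.12 * D, 0.5 * D, 0.88 * D])
    dist = np.minimum(np.abs(candidates - t0), np.abs(candidates - t1))
    dist[(candidates >= t0) & (candidates <= t1)] = -1.0
    anchor_pos = candidates[np.argsort(dist)[-2:]]
    anchor_amp = 2.0  # > max planted-bump superposition, incl. jitter margin

    width = t1 - t0
    sigma = max(width / 8.0, 1.5 / config.sampling_rate)
    templates = []
    for cid in range(config.n_classes):
        centers = np.concatenate(
            [np.tile(anchor_pos, (N_CHANNELS, 1)), np.zeros((N_CHANNELS, K))], axis=1)
        widths = np.concatenate(
            [np.full((N_CHANNELS, 2), 0.06 * D), np.full((N_CHANNELS, K), sigma)], axis=1)
        amps = np.concatenate(
            [np.tile([anchor_amp, -anchor_amp], (N_CHANNELS, 1)),
             np.zeros((N_CHANNELS, K))], axis=1)
        # class-specific bumps, hard-masked to the window; centres shared
        # within a site pair as for every template
        windowed = np.zeros((N_CHANNELS, 2 + K), dtype=bool)
        windowed[:, 2:] = True
        for s in range(N_SITES):
            mu = rng.uniform(t0 + 2 * sigma, max(t1 - 2 * sigma, t0 + 2 * sigma + 1e-9), K)
            centers[2 * s, 2:] = mu
            centers[2 * s + 1, 2:] = mu
        for c in channels:
            amps[c, 2:] = rng.choice([-1.0, 1.0], K) * rng.uniform(0.4, 0.8, K)
        templates.append(WordTemplate(cid, centers, widths, amps,
                                      window=(t0, t1), window_channels=channels,
                                      windowed=windowed))
    return templates
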