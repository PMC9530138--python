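# Methods

This note documents the models, defaults and design decisions behind
`strainspeech`: what the synthetic generator does and does not emulate, how
the classifier and the explanation method are defined, and the numerical
choices that make runs reproducible.

## Transduction model

A gauge is described by (ν, π, E, η, R0) with gauge factor G = 1 + 2ν + πE
and relaxation time τ = η/E. Transduction is linearized as ΔR/R = G·ε with a
constant G over the elastic range |ε| ≤ 0.3; inputs outside that range are
rejected rather than extrapolated. The voltage-divider readout places the
gauge on the supply side with the fixed resistor to ground and reads
V = Vs·Rf/(R+Rf); the inverse conversion shares the same topology, so the
pair is an exact algebraic inverse (round-trip error < 1e-10 relative,
enforced by test). Supply voltage defaults to 3 V; R0 and Rf are free
config-level parameters — no measured values exist for them, and nothing
downstream depends on their absolute scale.

## Synthetic recordings

Each word class is a `WordTemplate`: per channel, K = 3 Gaussian bumps with
centres uniform in the middle 80% of the 2 s utterance, widths 80–250 ms
(the time scale of articulation gestures), amplitudes 0.3–1.2 in |ΔR/R|
with random sign. The two orthogonal gauges of one site share bump centres —
they are glued to the same patch of skin — but differ in width and
amplitude; this is what makes the H=2 axis of the tensor informative.

A repetition of a template is

    w_c(t) = (1+A)·Σ_k a_ck·exp(−(t−μ_ck−Δ)²/2σ_ck²) + drift_c(t) + noise_c(t)

with one timing shift Δ ~ N(0, 50 ms) shared by all channels of the record
(articulation shifts the whole face at once), amplitude jitter
A ~ N(0, 0.1), a slow sinusoid (0.1–0.5 Hz, amplitude ≤ 0.05) as baseline
drift, and white sensor noise (default sd 0.02, i.e. ~2% of a typical bump).
Additional subjects receive per-channel amplitude factors (sd 0.1) and
per-site centre offsets (sd 20 ms), mimicking sensor-placement and user
dependency. Defaults mirror the recording protocol the simulator emulates
(100-word vocabulary, 100 repetitions per word over two subjects, 300 Hz,
2 s); tests and the acceptance script use smaller vocabularies, stated
below. No quantitative repetition-variability measurements exist for the
real recordings; the jitter magnitudes were chosen once to produce visibly
repeatable but non-identical traces and are config parameters, not fitted
quantities.

RNG discipline: one root seed; templates, subject effects and each record
draw from child streams keyed by (seed, purpose, record index), so any
record is reproducible independently of generation order and the whole
dataset is a pure function of its config.

What the generator does **not** emulate: real articulation dynamics (bump
shapes are symmetric Gaussians), inter-channel mechanical cross-talk beyond
shared bump timing, electrode drift over sessions, or the actual acoustic
similarity structure of words. Passing tests therefore demonstrate that the
pipeline's machinery is correct and sensitive in the intended directions,
not that the real-recording accuracies are reproduced; the printed
real-data numbers require the physical devices and human subjects and are
out of scope.

### Planted-window fixtures

`plant_discriminative_window` builds datasets whose class information is
confined to a known time window and channel subset — the ground truth
against which attribution maps and channel ablation are validated. A subtle
leak had to be engineered away: per-channel min–max normalization estimates
its constants from the whole trace, so class-specific bumps that set a
channel's min or max rescale the *entire* channel in a class-dependent way,
leaking label information outside the window (empirically: zeroing the
window at test time left a CNN at 80% on a 4-class task instead of 25%).
The shared waveform is therefore a pair of large fixed anchor bumps
(amplitude ±2, far from the window) that pin every channel's min and max;
class bumps (|a| ≤ 0.8) never reach the extremes, the normalization
constants become class-independent, and occluding the window drops accuracy
to chance.

## Preprocessing

Per channel: min–max normalization to [0, 1] (constant traces map to zeros
to avoid 0/0 and are logged as degenerate), Savitzky–Golay smoothing, then
linear-interpolation resampling onto a fixed uniform grid. The normalize →
smooth order is the default; since smoothing a normalized trace can
overshoot [0, 1] slightly at sharp features, the result is clipped back
(clipped mass logged at DEBUG). The smooth-first order, which makes
clipping a no-op, is available via `normalize_first=False`.

Filter defaults: window 15 samples (50 ms at 300 Hz), polynomial order 3 —
wide enough to suppress white sensor noise, narrow enough to preserve
~100 ms articulation bumps. Edges are mirror-padded (no endpoint bias).
These parameters are not recorded for the original system; they are exposed
in `PreprocessConfig`.

Tensor layout: row 0 holds the horizontal gauges of sites S1..S4 in
left-to-right site order, row 1 the vertical gauges in the same order, so
spatially adjacent sites occupy adjacent tensor columns; the mapping is
recorded in `channel_map` and is invertible (tested as a bijection).

The pipeline is *approximately* idempotent: normalization and regridding
are exact fixed points on processed data, but a Savitzky–Golay filter is
not a projection, so re-running the pipeline attenuates the sharpest peaks
by up to ~10% of the range (tested with an explicit tolerance).

## Classifier

Architecture: 7 × (conv3d → instance norm → ReLU), then flatten → FC →
ReLU → FC → ReLU → FC. All convolutions use kernel (3,3,3), padding
(1,1,1), stride (1,1,1) except Conv3 — kernel (3,1,3), padding (1,0,1),
stride (2,1,2) — which halves H (2→1) and T and keeps the W=4 site axis.
No pooling anywhere, preserving localized spatial information. The printed
kernel triples are read on the (H, W, T) axes in that order, matching the
input definition X ∈ R^{1×H×W×T}; the alternative (T, H, W) reading is
implemented behind `axis_order='thw'` since the original description does
not disambiguate it. Instance normalization standardizes each (sample,
feature-channel) over (H, W, T) with ε = 1e-5 and no affine parameters.

Channel widths (8, 16, 16, 32, 32, 64, 64) and FC sizes (256, 128,
n_classes) are this package's defaults, sized for CPU training (the
original per-layer table is not public); desk-scale experiments use the
narrower (4, 8, 8, 8, 8, 16, 16)/(64, 32) with inputs resampled to T = 60,
which preserves the full architecture geometry while training in seconds.
Training: softmax cross-entropy, Adam (lr 1e-3 default, 2e-3 at desk
scale), batch 16 (8 at desk scale), seeded init and batch shuffling — two
runs with one seed produce bit-identical training logs on one machine. Ties
in argmax resolve to the lowest class index everywhere.

The network is implemented directly in numpy: convolutions are evaluated
tap-by-tap (one strided slice + tensordot per kernel offset), which is
efficient at these spatial sizes and keeps the backward pass and the
relevance-propagation transpose structurally symmetric. All gradients are
verified against central finite differences in the test suite.

Baselines: the correlation classifier assigns each query the class of the
most cosine-similar reference recording (the protocol rotates every
repetition group in as the reference set and averages the per-group
accuracies); the SVM baseline is a linear-kernel SVC (C = 1) on flattened
preprocessed tensors — the conservative reading of a "conventional SVM".

## Evaluation protocols

Cross-validation uses stratified, seeded folds (at 20 records per class an
unstratified shuffle can leave a fold without a class entirely); the mean
of per-fold accuracies is reported, not the pooled accuracy. The learning
curve fixes the last fold as the test set and samples stratified training
subsets of each requested size. Channel ablation zero-masks the complement
of each channel subset and retrains per subset by default (the
interpretation consistent with reporting per-subset accuracies);
mask-at-inference-only is available as a cheap screening mode, and the
subset list can be restricted when exhaustive enumeration at CNN cost is
not affordable. Transfer adaptation freezes the convolution stack and
fine-tunes the FC layers for 20 epochs at one tenth of the training rate —
the standard few-shot recipe for a re-attached sensor or a new subject.
SNR is defined as RMS(active segment)/RMS(rest segment); no formula was
published for the original measurement, and the RMS ratio is the
conventional choice.

A methodological note on chance-floor controls: permuting labels *without
replacement* makes the labels of near-identical repetitions negatively
dependent, so a classifier that memorizes repetition clusters lands
systematically *below* chance (measured: 9% on a 5-class task). The
package's chance-floor experiments therefore equalize templates across
classes (inputs carry no label information), which yields accuracies inside
the binomial interval around 1/n_classes for all three classifiers.

## Explanation

R-CAM: the target-class logit is propagated back to a chosen convolution
layer with ε-rule layer-wise relevance propagation (ε = 1e-6; linear and
conv layers redistribute R_in = x ⊙ Wᵀ(R_out/(z + ε·sign z)); ReLU and
instance norm pass relevance through; flatten reshapes). The map is the
positive part of the relevance-weighted activations of that layer, linearly
upsampled along T to the input length and min–max normalized.

Two weightings are provided. The channel-global variant (one weight per
feature channel = its summed relevance) follows the classic CAM recipe but,
at these tiny spatial grids, re-introduces activation mass everywhere a
weighted channel is active: on planted-window ground truth it concentrates
only ~0.2 of its mass in a 20%-of-duration window — indistinguishable from
uniform — at every source layer. The default is therefore the elementwise
weighting (relevance × activation per cell, summed over channels), which
preserves the spatial structure of the propagated relevance and reaches
~0.6 mass in the planted window; the default source layer is the last
convolution layer (Conv7), whose receptive fields carry class evidence
while still resolving half the input frames. A Grad-CAM-style
gradient-weighted variant is available via `method='grad'`. The weighting
and layer are recorded in each map's metadata.

t-SNE and silhouette scoring delegate to scikit-learn; the silhouette
wrapper applies the standard s(i) = 0 convention to singleton clusters
instead of raising.

## Problem sizes

Desk-scale experiments (tests and `scripts/acceptance.py`) use 4–5 classes
with 12–20 repetitions, inputs resampled to T = 60, and the narrow CNN
above; the full acceptance run completes in a few minutes on one CPU and
every stochastic stage derives its seed from the single `--seed` argument.

## Known limitations

- Synthetic waveforms are sums of Gaussians; none of the results transfer
  claims about real articulation dynamics.
- The numpy CNN is CPU-oriented; at the full 100-word, T = 600 scale,
  training would be slow (the architecture itself is unchanged, only
  widths/length are scaled in the experiments here).
- ε-LRP through instance normalization treats the normalization as
  identity; relevance conservation is therefore approximate.
- The correlation classifier requires every class in each reference group;
  incomplete groups are an error rather than being skipped.
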