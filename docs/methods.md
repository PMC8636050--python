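# Methods

## Problem and model

The package predicts one of four lower-limb movements — sit, stand, walk,
go-upstairs — from 12-channel upper-limb surface EMG recorded during the 2 s
*movement-preparation* posture that precedes each movement, sampled at
1500 Hz. The intended user is a movement-prediction interface for a
walking-assist exoskeleton, where lower-limb EMG is unavailable (paraplegic
wearers) and upper-limb activity during preparation carries the intent.

The core classifier is a channel-synergy network operating on 200 ms
(300-sample) windows `X ∈ R^{C×L}`, C = 12, L = 300:

1. **Channel-wise LSTM.** Each channel's scalar sequence runs through its
   own LSTM (hidden size 300); the final hidden state becomes that channel's
   timing-feature row, giving `F_temp ∈ R^{C×300}`. Channels `k` and
   `k + C/2` are the left/right symmetric electrode pair over the same
   muscle; their LSTMs share one weight bank, which halves the recurrent
   parameters and builds the mirror symmetry of the montage into the model.
2. **Spatiotemporal convolutions.** F1 = 12 temporal filters of shape
   (1, 65), same-padded, produce `F_conv ∈ R^{F1×C×300}`; a depthwise
   spatial convolution of shape (C, 1) with depth multiplier D = 2 collapses
   the electrode axis into F2 = D·F1 = 24 learned spatial patterns,
   `F_dconv ∈ R^{24×1×300}`.
3. **Separable convolution.** A per-map depthwise (1, 15) filter followed by
   F2 pointwise (1, 1) mixers; size-preserving (this forces F2 = D·F1),
   extracting cross-map "synergy" combinations.
4. **Channel attention.** Average- and max-pool each of the F2 maps over its
   length, pass both pooled vectors through a shared 2-layer MLP (hidden
   F2/r, r = 4, ReLU), add, and squash:
   `w = σ(MLP(avg) + MLP(max)) ∈ (0, 1)^{F2}`; the maps are rescaled by `w`
   before the flatten + softmax head.

ELU follows every convolutional block. There is no batch norm, dropout or
pooling. Training is Adam (lr 1e-3, β = 0.9/0.999) on class-weighted
cross-entropy; weights are the inverse class frequency of the training
labels with the majority class pinned at 1 (walking has twice the trials of
the other movements). Batches are 10 temporally consecutive windows of one
trial; batch order is reshuffled every epoch. Validation stopping keeps the
weights with the lowest validation loss over the epoch budget.

Two deep baselines reuse the same layers: **TCNN** (temporal + depthwise
convolution + softmax on raw windows) and **CNN-LSTM** (two stacked
channel-wise LSTM layers, then temporal, depthwise and separable-depthwise
stages + softmax). Seven classical baselines (LDA, decision tree,
kernel-density naive Bayes, linear/RBF SVM, 1-NN Mahalanobis, 28-unit MLP)
operate on per-window features: MAV, waveform length, zero crossings,
order-6 Burg AR coefficients, and mean Welch PSD over 10–450 Hz — ten
numbers per channel.

## Numerics and implementation choices

- The networks are implemented directly in NumPy with hand-derived
  gradients (`synergynet.nn`): batched-per-unit LSTM BPTT, im2col temporal
  convolutions, einsum depthwise/pointwise stages, and an explicit
  channel-attention backward. Backward passes are validated against central
  differences at 1e-4 relative tolerance in the test suite; all math is
  float64.
- Initialization: uniform Glorot for convolution/dense weights, per-gate
  orthogonal recurrent matrices, forget-gate bias 1, everything drawn from
  one seeded generator; training is bit-reproducible given the seed.
- Filters: 4th-order Butterworth bandpass (10–450 Hz) and an IIR notch at
  50 Hz with Q = 30, both applied forward–backward (zero phase), once per
  trial before cropping and windowing, never per window. Band edges are
  validated against Nyquist.
- Windowing discards a trailing partial window; the count is
  `floor((T − L)/step) + 1`.
- Zero crossings use strict opposite signs with an optional dead-band
  (default 0). Burg AR follows the sign convention `x_t ≈ Σ a_j x_{t−j}`;
  constant inputs yield a zero vector with a warning so silent channels
  survive batch extraction. Welch PSD uses a Hann window, segment 128, 50 %
  overlap; the estimator is pinned by a Parseval check in the tests.
- NMF is multiplicative-update on the Frobenius objective with a fixed seed
  and iteration cap; the objective is asserted non-increasing at every
  update. Activations are rectified (absolute value) before factorization.
  Dominant channels are those whose basis loading exceeds τ = 0.5 of the
  largest loading.
- Information-flow tracing: per spatial filter, the fraction of absolute
  depthwise weight mass on the dominant source channels; filters above the
  median fraction form the flow set, propagated through the separable
  pointwise weights the same way. Attention-top is the top quartile of
  attention weights averaged over an evaluation batch; agreement is the
  Jaccard overlap of the final flow set with it.
- Splits are at the **trial** level (windows overlap at stride 100, so
  window-level splits would leak). Within-subject: stratified 70/30 with
  4-fold CV over the 70 % supplying validation sets; accuracy on the held-out
  30 %. Cross-subject: (3 train, 2 validation) subject partitions. Ablation
  retrains all four conditions (full, −depthwise, −separable, −attention)
  on identical splits and seeds, verified by a split hash; shape
  reconciliation after a removal is parameter-free (a plain channel average
  replaces the depthwise stage; the other removals are pass-throughs).
- Class weights that cannot be honored are dropped silently only where the
  estimator offers no hook (1-NN, MLP baseline); SVMs, tree and LDA priors
  receive them.

## The synthetic cohort

The simulator (`synergynet.synthgen`) generates the study conditions:
12 channels, 1500 Hz, 2 s preparation segments annotated as such, four
classes with 10/10/20/10 trials per subject (walking doubled). Channel `c`
of a class-`m` trial is amplitude-modulated band-limited Gaussian noise —
the standard interference-pattern surrogate for surface EMG:

    x_c(t) = loading[c, m] · gain_c · env(t) · carrier_c(t) + mains + floor

with a 20–450 Hz unit-RMS carrier that shares a common component with the
symmetric partner channel (weight 0.4), a 0.2 s ramp-up/plateau/ramp-down
envelope, a 50 Hz mains sinusoid (amplitude 0.2), and white noise (0.05).
Each class activates two symmetric muscle pairs at loading 1.0 over a 0.15
background; the *planted channels* (loading > half the class maximum) are
the ground truth for the explainability tests. Per-subject muscle
compensation is a lognormal multiplicative perturbation of the loadings
(σ = 0.15) plus a small per-channel gain spread; increasing it measurably
degrades cross-subject transfer. All randomness descends from one master
seed through named per-subject/per-trial substreams.

What the simulator does **not** emulate: motor-unit physiology, electrode
artifacts, nonstationary fatigue effects, and — importantly — whatever
real-data structure makes every network block individually necessary.
Classes differ in which channels co-activate, a structure that several
model variants (and even an RMS nearest-centroid rule) can exploit, so
passing tests demonstrate pipeline correctness and recoverable synergy
structure, not real-data performance levels.

## Desk-scale study sizes

The end-to-end studies (`synergynet.studies`) run a reduced configuration:
100-sample windows, LSTM hidden 32, F1 = 4, D = 2 (F2 = 8), kernels 17/7,
attention reduction 4 — same topology and ratios as the full (2, 12, 300)
network, which is still used for all architecture-contract checks. Cohorts
are 1 subject × 3 trials/class (learning study, 100 epochs, high SNR:
noise 0.02, no inter-subject perturbation) and 5 subjects × 2 trials/class
(ablation study, 25 epochs — past the observed best epochs of 8–28 — and
3 seeds on one shared subject partition; synergy studies, 30 epochs,
5 seeds). These sizes are the package's study design for CPU-scale
reproducibility.

## Known limitations

- **Ablation ordering.** On synthetic cohorts the full network reliably
  beats the depthwise- and separable-removed variants, but the
  attention-removed variant matches the full model to within seed noise and
  sometimes exceeds it (observed across epoch budgets 10–50 and
  perturbation scales 0.15–0.7; the ordering holds or fails depending on
  the cohort/training seed). The planted class structure is separable without
  per-window gating, so the attention block adds optimization burden
  without adding usable signal at this scale; the full ordering reported on
  real recordings should not be expected to reproduce on this simulator,
  and the corresponding acceptance test documents this as an open failure
  rather than weakening the assertion.
- **Attention-vs-flow agreement.** The agreement statistic is coarse
  (median/quartile cuts on 8 maps) and initialization-sensitive at short
  training; the trained-vs-shuffled-control comparison holds on the
  committed design but with a small margin.
- Accuracy *levels* on synthetic cohorts are not comparable to levels on
  the real recordings; only the qualitative orderings (within ≥ cross,
  signal ≫ shuffled) are meaningful.
- The CNN-LSTM and TCNN layer widths beyond the shared dimensions are this
  package's choices; only their block structure is fixed by the comparison
  design.
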