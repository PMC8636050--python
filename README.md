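# synergynet

Channel-synergy movement prediction from surface EMG.

Walking-assist exoskeletons for paraplegic users cannot read movement intent
from lower-limb muscles — those signals are absent.  This package implements
an interface that predicts the intended lower-limb movement (sit, stand,
walk, go upstairs) from **12-channel upper-limb sEMG** recorded during the
2 s *movement-preparation* posture, together with the classical and deep
baselines it is compared against, an NMF-based muscle-synergy
explainability analysis, and a synthetic sEMG simulator with planted
synergy ground truth so the whole pipeline is testable without any
recordings.

## The model

Windows `X ∈ R^{C×L}` (C = 12 channels, L = 300 samples = 200 ms at
1500 Hz, stride 100) pass through four blocks:

1. **Channel-wise LSTM** — one LSTM per electrode (hidden 300); left/right
   symmetric electrode pairs (k, k + C/2) share weights.  Final hidden
   states form the timing features `F_temp ∈ R^{C×300}`.
2. **Spatiotemporal convolutions** — F1 = 12 temporal filters (1, 65), then
   a depthwise spatial convolution (C, 1) with depth multiplier D = 2,
   collapsing the electrode axis into F2 = 24 learned spatial patterns.
3. **Separable convolution** — depthwise (1, 15) + F2 pointwise mixers,
   size-preserving, extracting cross-map synergy combinations.
4. **Channel attention** — `w = σ(MLP(AvgPool(F)) + MLP(MaxPool(F)))`
   gates each feature map with a weight in (0, 1) before flatten + softmax.

Training: Adam on class-weighted cross-entropy (inverse class frequency,
majority = 1), batches of 10 consecutive windows of one trial, validation
stopping.  Everything — including LSTM backpropagation-through-time and the
convolution/attention gradients — is implemented in NumPy and verified
against numerical gradients; see `docs/methods.md` for the numerics.

Also included: TCNN and CNN-LSTM deep baselines built from the same layers;
LDA / decision-tree / kernel-density naive Bayes / linear & RBF SVM /
Mahalanobis 1-NN / MLP baselines on MAV, waveform-length, zero-crossing,
Burg-AR(6) and Welch-PSD features; within-subject (70/30 + 4-fold CV) and
cross-subject (3 train / 2 validation subjects) protocols; a layer-ablation
study; and information-flow tracing from NMF-dominant input channels
through the learned weights to the attention module.

## Worked example

```python
import numpy as np
from synergynet import (
    SimConfig, generate_cohort, load_dataset, FilterSpec, build_windows,
    MCSNetConfig, TrainConfig, build_model, train_model, predict_labels,
    accuracy, channel_contribution_nmf, planted_channels, jaccard, MovementLabel,
)

# simulate one subject: 3 trials per movement, high signal-to-noise
sim = SimConfig(n_subjects=1, seed=0, trials_per_class={m: 3 for m in range(4)},
                loading_perturbation=0.0, noise_floor=0.02)
manifest, truth = generate_cohort(sim)
recs = load_dataset(manifest)["S00"]

# notch + bandpass, crop the 2 s preparation period, segment into windows
ws = build_windows(recs, FilterSpec(), window_len=100, step=150)
print(f"{len(ws)} windows of shape {ws.windows.shape[1:]} from {len(recs)} trials")

# hold out one trial per class; train the desk-scale network
trials = ws.trial_ids.astype(str)
test_mask = np.array([t.endswith("_02") for t in trials])
val_mask = np.array([t.endswith("_01") for t in trials])
cfg = MCSNetConfig.scaled()
model = build_model("MCSNet", cfg, seed=0)
trained = train_model(model, ws.subset(~test_mask & ~val_mask), ws.subset(val_mask),
                      TrainConfig(epochs=30, batch=10, seed=0))
test = ws.subset(test_mask)
print(f"best epoch {trained.best_epoch}, held-out accuracy "
      f"{accuracy(predict_labels(trained.model, test), test.labels):.3f}")

# which channels drive the sitting movement? NMF on the class-averaged signal
sit = ws.subset(ws.labels == int(MovementLabel.SIT))
dec = channel_contribution_nmf(np.abs(sit.windows).mean(axis=0), k=1)
planted = planted_channels(truth, MovementLabel.SIT)
print(f"dominant channels {sorted(dec.dominant_channels)}, planted {planted}, "
      f"Jaccard {jaccard(dec.dominant_channels, planted):.2f}")
```

Output:

```
240 windows of shape (12, 100) from 12 trials
best epoch 25, held-out accuracy 0.963
dominant channels [0, 1, 6, 7], planted [0, 1, 6, 7], Jaccard 1.00
```

The held-out accuracy shows the scaled network recovering the planted
class structure from filtered windows; the NMF decomposition of the
class-averaged rectified signal identifies exactly the channels the
simulator activated for the sitting movement.

A `synergynet` command-line tool wraps the same pipeline
(`simulate`, `inspect`, `preprocess`, `features`, `train`, `protocol`,
`ablate`, `synergy`); run `synergynet --help`.

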