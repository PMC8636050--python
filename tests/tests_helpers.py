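"""Tiny shared constructions for model-level tests."""

import numpy as np

from synergynet import MCSNetConfig
from synergynet.io import WindowSet


def tiny_config() -> MCSNetConfig:
    return MCSNetConfig(
        n_channels=2, window_len=16, lstm_hidden=8, f1=2, temporal_kernel=5,
        depth=1, separable_kernel=3, attention_reduction=2, n_classes=4,
    )


def tiny_windows(seed: int, n_trials: int = 4, per_trial: int = 6,
                 C: int = 2, L: int = 16) -> WindowSet:
    """Synthetic windows with class-dependent channel amplitude."""
    rng = np.random.default_rng(seed)
    windows, labels, trials, order = [], [], [], []
    for t in range(n_trials):
        label = t % 4
        amp = 0.3 + 0.6 * np.array([label % 2, label // 2])
        for i in range(per_trial):
            windows.append(amp[:, None] * rng.standard_normal((C, L)))
            labels.append(label)
            trials.append(f"s/t{t}")
            order.append(i)
    return WindowSet(np.stack(windows), labels, ["s"] * len(labels), trials, order, {})
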