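"""Shared fixtures: small synthetic cohorts and a tiny trained model."""

from __future__ import annotations

import numpy as np
import pytest

from synergynet import (
    FilterSpec,
    MCSNetConfig,
    SimConfig,
    TrainConfig,
    build_model,
    generate_cohort,
    load_dataset,
    train_model,
)
from synergynet.evaluate import _subject_windows


@pytest.fixture(scope="session")
def small_cohort():
    """One subject, two trials per class, high SNR; dataset + ground truth."""
    sim = SimConfig(
        n_subjects=1, seed=0, trials_per_class={m: 2 for m in range(4)},
        loading_perturbation=0.0, noise_floor=0.02, mains_amplitude=0.1,
    )
    manifest, gt = generate_cohort(sim)
    return load_dataset(manifest), gt, sim


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """Preprocessed non-overlapping 100-sample windows of the small cohort."""
    dataset, _gt, _sim = small_cohort
    return _subject_windows(dataset, ["S00"], FilterSpec(), window_len=100, step=300)


@pytest.fixture(scope="session")
def tiny_trained(small_windows):
    """A briefly trained scaled network (shared by model/synergy tests)."""
    ws = small_windows
    trials = ws.trial_ids.astype(str)
    val_mask = np.array([t.endswith("_01") for t in trials])
    train_ws, val_ws = ws.subset(~val_mask), ws.subset(val_mask)
    cfg = MCSNetConfig.scaled()
    model = build_model("MCSNet", cfg, seed=0)
    trained = train_model(model, train_ws, val_ws, TrainConfig(epochs=10, batch=10, seed=0))
    return trained, train_ws, val_ws, ws
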