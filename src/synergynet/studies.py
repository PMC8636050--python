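"""Reproducibility studies: the end-to-end experiments at desk scale.

Each function runs one complete scaled experiment — simulate a cohort,
preprocess, train, evaluate — and returns its headline numbers.  These are
the experiments the acceptance machinery executes; problem sizes are the
package's desk-scale study design (see docs/methods.md): the reduced
architecture (:meth:`MCSNetConfig.scaled`), small cohorts, and non- or
lightly-overlapping windows, with every random draw derived from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .evaluate import (
    SplitPlan,
    _subject_windows,
    _trials_subset,
    accuracy,
    make_splits,
    run_ablation,
)
from .io import WindowSet
from .mcsnet import MCSNetConfig, TrainConfig, build_model, predict_labels, train_model
from .preprocess import FilterSpec
from .synergy import (
    channel_contribution_nmf,
    jaccard,
    layer_activation_nmf,
    trace_information_flow,
)
from .synthgen import SimConfig, generate_cohort, planted_channels
from .io import load_dataset

__all__ = [
    "end_to_end_learning_study",
    "ablation_study",
    "synergy_recovery_study",
    "attention_flow_agreement_study",
]

#: high-SNR single-subject conditions for the learning study
_HIGH_SNR = dict(loading_perturbation=0.0, noise_floor=0.02, mains_amplitude=0.1)


def _shuffle_trial_labels(sets: list[WindowSet], seed: int) -> list[WindowSet]:
    """Permutation null: permute labels at the *trial* level across all sets.

    Shuffling whole trials (rather than windows) preserves the batch
    structure and breaks every label-signal association, including the one
    validation stopping could otherwise exploit.
    """
    rng = np.random.default_rng(seed + 100)
    trial_label: dict[str, int] = {}
    for ws in sets:
        for t, l in zip(ws.trial_ids.astype(str), ws.labels):
            trial_label.setdefault(t, int(l))
    trials = sorted(trial_label)
    permuted = rng.permutation([trial_label[t] for t in trials])
    mapping = dict(zip(trials, permuted))
    out = []
    for ws in sets:
        shuffled = ws.subset(np.arange(len(ws)))
        shuffled.labels = np.array([mapping[t] for t in shuffled.trial_ids.astype(str)])
        out.append(shuffled)
    return out


def end_to_end_learning_study(seed: int = 0, epochs: int = 100) -> dict:
    """Within-subject learning on a high-SNR single-subject cohort.

    Trains the scaled network for ``epochs`` epochs (batch 10, validation
    stopping on fold 0 of the 4-fold CV) and evaluates on the held-out 30%
    of trials; a label-shuffled control model is trained identically.
    Returns the held-out accuracies and the chance band.
    """
    sim = SimConfig(n_subjects=1, seed=seed,
                    trials_per_class={m: 3 for m in range(4)}, **_HIGH_SNR)
    manifest, _gt = generate_cohort(sim)
    dataset = load_dataset(manifest)
    cfg = MCSNetConfig.scaled()
    ws = _subject_windows(dataset, ["S00"], FilterSpec(), cfg.window_len, step=150)
    sp = make_splits(dataset, SplitPlan(mode="within", seed=seed))["S00"]
    fit_trials, val_trials = sp.folds[0]
    train_ws = _trials_subset(ws, "S00", fit_trials)
    val_ws = _trials_subset(ws, "S00", val_trials)
    test_ws = _trials_subset(ws, "S00", sp.test_trials)
    tc = TrainConfig(epochs=epochs, batch=10, seed=seed)

    trained = train_model(build_model("MCSNet", cfg, seed=seed), train_ws, val_ws, tc)
    test_acc = accuracy(predict_labels(trained.model, test_ws), test_ws.labels)

    shuf_train, shuf_val = _shuffle_trial_labels([train_ws, val_ws], seed)
    control = train_model(
        build_model("MCSNet", cfg, seed=seed), shuf_train, shuf_val, tc,
    )
    control_acc = accuracy(predict_labels(control.model, test_ws), test_ws.labels)

    n_classes = cfg.n_classes
    chance = 1.0 / n_classes
    se = float(np.sqrt(chance * (1 - chance) / len(test_ws)))
    return {
        "test_accuracy": test_acc,
        "control_accuracy": control_acc,
        "chance_level": chance,
        "chance_se": se,
        "n_test_windows": len(test_ws),
        "best_epoch": trained.best_epoch,
    }


def ablation_study(seed: int = 0, epochs: int = 25, n_seeds: int = 3) -> dict:
    """Cross-subject layer ablation on a 5-subject cohort, shared splits/seeds.

    Returns the mean validation-subject accuracy per condition ('none' plus
    each single-layer removal) averaged over ``n_seeds`` training seeds.
    """
    sim = SimConfig(n_subjects=5, seed=seed, trials_per_class={m: 2 for m in range(4)})
    manifest, _gt = generate_cohort(sim)
    dataset = load_dataset(manifest)
    cfg = MCSNetConfig.scaled()
    plan = SplitPlan(mode="cross", n_repetitions=1, seed=seed)
    tc = TrainConfig(epochs=epochs, batch=10, seed=seed)
    report = run_ablation(
        cfg, dataset, plan, tc, seeds=[seed + i for i in range(n_seeds)],
        window_len=cfg.window_len, step=300,
    )
    means = report.mean_accuracy()
    return {
        "mean_accuracy": {k: float(v) for k, v in means.items()},
        "cells": report.cells,
        "split_digest": report.split_digest,
    }


def synergy_recovery_study(seed: int = 0, n_seeds: int = 5) -> dict:
    """Planted-channel recovery by NMF on class-averaged rectified input.

    For ``n_seeds`` cohorts and all four movement classes, factor the
    class-averaged preprocessed windows (k = 1) and compare the dominant
    channels with the simulator's planted set.  Returns per-cohort and mean
    Jaccard overlap.
    """
    scores = []
    for i in range(n_seeds):
        sim = SimConfig(n_subjects=1, seed=seed + i,
                        trials_per_class={m: 2 for m in range(4)})
        manifest, gt = generate_cohort(sim)
        dataset = load_dataset(manifest)
        ws = _subject_windows(dataset, ["S00"], FilterSpec(), 300, step=300)
        per_class = []
        for m in range(4):
            avg = np.abs(ws.windows[ws.labels == m]).mean(axis=0)
            dec = channel_contribution_nmf(avg, k=1, seed=seed)
            per_class.append(jaccard(dec.dominant_channels, planted_channels(gt, m)))
        scores.append(float(np.mean(per_class)))
    return {"per_seed_jaccard": scores, "mean_jaccard": float(np.mean(scores))}


def attention_flow_agreement_study(seed: int = 0, epochs: int = 30, n_seeds: int = 5) -> dict:
    """Attention-vs-flow agreement for trained models vs label-shuffled controls.

    For each cohort seed, train the scaled network and an identically
    initialized model on shuffled labels; compute the information-flow /
    attention-top Jaccard agreement averaged over the four classes.
    """
    real, shuffled = [], []
    for i in range(n_seeds):
        s = seed + i
        sim = SimConfig(n_subjects=1, seed=s, trials_per_class={m: 2 for m in range(4)})
        manifest, _gt = generate_cohort(sim)
        dataset = load_dataset(manifest)
        cfg = MCSNetConfig.scaled()
        ws = _subject_windows(dataset, ["S00"], FilterSpec(), cfg.window_len, step=300)
        trials = ws.trial_ids.astype(str)
        val_mask = np.array([t.endswith("_01") for t in trials])
        train_ws, val_ws = ws.subset(~val_mask), ws.subset(val_mask)
        tc = TrainConfig(epochs=epochs, batch=10, seed=s)
        for shuffle in (False, True):
            if shuffle:
                tws, vws = _shuffle_trial_labels([train_ws, val_ws], s)
            else:
                tws, vws = train_ws, val_ws
            trained = train_model(build_model("MCSNet", cfg, seed=s), tws, vws, tc)
            ags = []
            for m in range(4):
                ws_c = ws.subset(ws.labels == m)
                dom = layer_activation_nmf(trained.model, ws_c, layer="input").dominant_channels
                ags.append(trace_information_flow(trained.model, dom, ws_c).agreement)
            (shuffled if shuffle else real).append(float(np.mean(ags)))
    return {
        "real_agreements": real,
        "shuffled_agreements": shuffled,
        "mean_real": float(np.mean(real)),
        "mean_shuffled": float(np.mean(shuffled)),
    }
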