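"""Evaluation protocols: within-subject, cross-subject, and layer ablation.

Splitting is always at the **trial** level — windows inherit their trial's
side — because the 100-sample stride makes neighboring windows overlap by
two-thirds, and window-level splitting would leak nearly identical samples
between train and test.

*Within-subject*: each subject's trials are split 70/30 (stratified by
class); 4-fold cross-validation over the 70% provides the validation sets
for stopping, and the reported accuracy is on the held-out 30%.

*Cross-subject*: repetitions of (3 training subjects, 2 validation
subjects); accuracy is on the validation subjects' windows, mirroring the
study protocol.

The ablation study retrains the full network and its three single-layer
removals on identical splits and seeds (enforced by a split hash).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import build_feature_matrix, configure_baseline, make_classifier
from .io import Recording, WindowSet
from .mcsnet import MCSNetConfig, TrainConfig, build_model, predict_labels, train_model
from .preprocess import FilterSpec, build_windows, compute_class_weights

__all__ = [
    "SplitPlan",
    "WithinSplit",
    "make_splits",
    "split_hash",
    "accuracy",
    "ResultsTable",
    "AblationReport",
    "DeepRunner",
    "FeatureRunner",
    "run_protocol",
    "run_ablation",
]


@dataclass(frozen=True)
class SplitPlan:
    """mode 'within' (70/30 + k-fold CV) or 'cross' ((3, 2) subject partitions)."""

    mode: str = "within"
    train_fraction: float = 0.7
    n_folds: int = 4
    n_train_subjects: int = 3
    n_val_subjects: int = 2
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("within", "cross"):
            raise ValueError("mode must be 'within' or 'cross'")


@dataclass
class WithinSplit:
    """Concrete trial-level split for one subject."""

    train_trials: list[str]
    test_trials: list[str]
    folds: list[tuple[list[str], list[str]]]  # (fit, validation) partitions of train


def _trial_table(dataset: dict[str, list[Recording]]) -> pd.DataFrame:
    rows = [
        {"subject": subj, "trial": rec.trial_id, "label": int(rec.label)}
        for subj, recs in sorted(dataset.items())
        for rec in recs
    ]
    return pd.DataFrame(rows)


def make_splits(dataset: dict[str, list[Recording]], plan: SplitPlan):
    """Deterministic concrete splits for a dataset under a plan.

    Returns ``{subject: WithinSplit}`` for 'within' or a list of
    ``(train_subjects, val_subjects)`` tuples for 'cross'.
    """
    table = _trial_table(dataset)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0xC]))
    if plan.mode == "within":
        out: dict[str, WithinSplit] = {}
        for subj in sorted(dataset):
            sub = table[table.subject == subj]
            train, test = [], []
            fold_of: dict[str, int] = {}
            for label, group in sub.groupby("label"):
                trials = sorted(group.trial)
                if len(trials) < 2:
                    raise ValueError(
                        f"subject {subj} class {label}: need >= 2 trials, got {len(trials)}"
                    )
                trials = [trials[i] for i in rng.permutation(len(trials))]
                n_train = max(1, min(len(trials) - 1, round(plan.train_fraction * len(trials))))
                train += trials[:n_train]
                test += trials[n_train:]
                # stratified fold assignment: spread each class over the folds
                offset = rng.integers(plan.n_folds)
                for i, t in enumerate(trials[:n_train]):
                    fold_of[t] = int((i + offset) % plan.n_folds)
            folds = []
            for f in range(plan.n_folds):
                val = sorted(t for t in train if fold_of[t] == f)
                fit = sorted(t for t in train if fold_of[t] != f)
                if val and fit:
                    folds.append((fit, val))
            out[subj] = WithinSplit(sorted(train), sorted(test), folds)
        return out
    subjects = sorted(dataset)
    need = plan.n_train_subjects + plan.n_val_subjects
    if len(subjects) < need:
        raise ValueError(f"cross-subject protocol needs >= {need} subjects, got {len(subjects)}")
    combos = []
    for train_set in itertools.combinations(subjects, plan.n_train_subjects):
        rest = [s for s in subjects if s not in train_set]
        for val_set in itertools.combinations(rest, plan.n_val_subjects):
            combos.append((list(train_set), list(val_set)))
    order = rng.permutation(len(combos))
    reps = [combos[i] for i in order[: plan.n_repetitions]]
    if len(reps) < plan.n_repetitions:  # sample with replacement beyond exhaustion
        extra = rng.integers(0, len(combos), size=plan.n_repetitions - len(reps))
        reps += [combos[i] for i in extra]
    return reps


def split_hash(splits) -> str:
    """Stable digest of a concrete split, for identity checks across runs."""

    def normalize(obj):
        if isinstance(obj, WithinSplit):
            return {"train": obj.train_trials, "test": obj.test_trials, "folds": obj.folds}
        if isinstance(obj, dict):
            return {k: normalize(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [normalize(v) for v in obj]
        return obj

    blob = json.dumps(normalize(splits), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def accuracy(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("cannot compute accuracy of empty predictions")
    return float(np.mean(pred == truth))


# --------------------------------------------------------------------------
# Model runners: a common fit/predict surface over deep nets and baselines
# --------------------------------------------------------------------------


class DeepRunner:
    """Trains one of the window-level networks under the shared protocol."""

    def __init__(self, arch: str, cfg: MCSNetConfig, tc: TrainConfig,
                 removed: str | None = None):
        self.name = arch if removed is None else f"{arch}-no-{removed}"
        self.arch, self.cfg, self.tc, self.removed = arch, cfg, tc, removed
        self.trained = None

    def fit(self, train: WindowSet, val: WindowSet) -> "DeepRunner":
        model = build_model(self.arch, self.cfg, seed=self.tc.seed, removed=self.removed)
        self.trained = train_model(model, train, val, self.tc)
        return self

    def predict(self, ws: WindowSet) -> np.ndarray:
        return predict_labels(self.trained.model, ws)


class FeatureRunner:
    """Feature extraction + one of the classical baseline classifiers."""

    def __init__(self, baseline: str, mode: str = "within", seed: int = 0):
        self.name = baseline.upper()
        self.spec = configure_baseline(baseline)
        self.mode, self.seed = mode, seed
        self.pipeline = None

    def fit(self, train: WindowSet, val: WindowSet | None = None) -> "FeatureRunner":
        X, y = build_feature_matrix(train)
        cw = compute_class_weights(y)
        self.pipeline = make_classifier(self.spec, cw, mode=self.mode, seed=self.seed)
        self.pipeline.fit(X, y)
        return self

    def predict(self, ws: WindowSet) -> np.ndarray:
        X, _ = build_feature_matrix(ws)
        return self.pipeline.predict(X)


# --------------------------------------------------------------------------
# Protocols
# --------------------------------------------------------------------------


def _subject_windows(dataset: dict[str, list[Recording]], subjects: Sequence[str],
                     spec: FilterSpec, window_len: int, step: int) -> WindowSet:
    recs = [r for s in subjects for r in dataset[s]]
    return build_windows(recs, spec, window_len=window_len, step=step)


def _trials_subset(ws: WindowSet, subject: str, trials: Sequence[str]) -> WindowSet:
    wanted = {f"{subject}/{t}" for t in trials}
    return ws.subset(np.isin(ws.trial_ids.astype(str), sorted(wanted)))


@dataclass
class ResultsTable:
    """Accuracy per model (rows) per subject/fold (columns) + mean and 2-SE."""

    cells: pd.DataFrame

    def with_summary(self) -> pd.DataFrame:
        out = self.cells.copy()
        vals = self.cells.to_numpy(dtype=float)
        out["mean"] = np.nanmean(vals, axis=1)
        n = np.sum(~np.isnan(vals), axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1) if vals.shape[1] > 1 else np.zeros(len(out))
        out["sem2"] = 2.0 * sd / np.sqrt(np.maximum(n, 1))
        return out


def run_protocol(
    runner_factories: dict[str, Callable[[], object]],
    dataset: dict[str, list[Recording]],
    plan: SplitPlan,
    filter_spec: FilterSpec | None = None,
    window_len: int = 300,
    step: int = 100,
) -> ResultsTable:
    """Train/evaluate each model under the plan; cells are fold-averaged accuracy.

    ``runner_factories`` maps model name -> zero-argument factory producing a
    fresh runner (so every cell trains from scratch).  Row order of the
    output equals the input order; a per-cell training failure is recorded as
    NaN rather than aborting the run.
    """
    spec = filter_spec or FilterSpec()
    splits = make_splits(dataset, plan)
    results: dict[str, dict[str, float]] = {name: {} for name in runner_factories}
    if plan.mode == "within":
        for subj in sorted(dataset):
            ws = _subject_windows(dataset, [subj], spec, window_len, step)
            sp = splits[subj]
            test_ws = _trials_subset(ws, subj, sp.test_trials)
            for name, factory in runner_factories.items():
                fold_accs = []
                for fit_trials, val_trials in sp.folds:
                    try:
                        runner = factory()
                        runner.fit(
                            _trials_subset(ws, subj, fit_trials),
                            _trials_subset(ws, subj, val_trials),
                        )
                        fold_accs.append(accuracy(runner.predict(test_ws), test_ws.labels))
                    except Exception:  # recorded, not fatal
                        fold_accs.append(np.nan)
                results[name][subj] = float(np.nanmean(fold_accs))
    else:
        for rep, (train_subjects, val_subjects) in enumerate(splits):
            train_ws = _subject_windows(dataset, train_subjects, spec, window_len, step)
            val_ws = _subject_windows(dataset, val_subjects, spec, window_len, step)
            for name, factory in runner_factories.items():
                try:
                    runner = factory()
                    runner.fit(train_ws, val_ws)
                    acc = accuracy(runner.predict(val_ws), val_ws.labels)
                except Exception:
                    acc = np.nan
                results[name][f"fold{rep}"] = float(acc)
    cells = pd.DataFrame(results).T.reindex(list(runner_factories))
    return ResultsTable(cells=cells)


@dataclass
class AblationReport:
    """Accuracy of the full network and each single-layer removal on shared splits."""

    cells: pd.DataFrame  # rows: removed layer ('none', ...), columns: folds
    split_digest: str = ""
    seeds: list[int] = field(default_factory=list)

    def mean_accuracy(self) -> pd.Series:
        return self.cells.mean(axis=1)


def run_ablation(
    cfg: MCSNetConfig,
    dataset: dict[str, list[Recording]],
    plan: SplitPlan,
    tc: TrainConfig,
    seeds: Sequence[int] = (0,),
    filter_spec: FilterSpec | None = None,
    window_len: int = 300,
    step: int = 100,
) -> AblationReport:
    """Retrain {full, -depthwise, -separable, -attention} on identical cross-subject splits.

    Every condition sees the same concrete splits (verified by hash) and the
    same seeds, so accuracy differences isolate the removed computation.
    """
    if plan.mode != "cross":
        raise ValueError("the ablation study uses the cross-subject protocol")
    spec = filter_spec or FilterSpec()
    splits = make_splits(dataset, plan)
    digest = split_hash(splits)
    conditions = [None, "depthwise", "separable", "attention"]
    cells: dict[str, dict[str, float]] = {
        ("none" if c is None else c): {} for c in conditions
    }
    for rep, (train_subjects, val_subjects) in enumerate(splits):
        train_ws = _subject_windows(dataset, train_subjects, spec, window_len, step)
        val_ws = _subject_windows(dataset, val_subjects, spec, window_len, step)
        for cond in conditions:
            key = "none" if cond is None else cond
            for seed in seeds:
                tc_seed = TrainConfig(epochs=tc.epochs, batch=tc.batch, lr=tc.lr, seed=seed)
                runner = DeepRunner("MCSNet", cfg, tc_seed, removed=cond)
                runner.fit(train_ws, val_ws)
                acc = accuracy(runner.predict(val_ws), val_ws.labels)
                cells[key][f"fold{rep}_seed{seed}"] = acc
    frame = pd.DataFrame(cells).T
    return AblationReport(cells=frame, split_digest=digest, seeds=list(seeds))
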