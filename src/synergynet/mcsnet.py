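"""The channel-synergy movement-prediction network and its deep baselines.

The main model maps a ``(C, L)`` sEMG window to one of N movement classes in
four blocks:

1. channel-wise LSTM (symmetric-pair weight sharing) — each electrode's
   sample sequence becomes a ``lstm_hidden``-dimensional timing-feature row,
   giving ``F_temp`` of shape ``(C, H)``;
2. a bank of F1 temporal filters (1, 65) followed by a depthwise spatial
   convolution (C, 1) with depth multiplier D — ``(D*F1, 1, H)`` learned
   spatiotemporal maps;
3. a separable convolution — depthwise (1, 15) then F2 = D*F1 pointwise
   mixers — extracting channel-synergy features at unchanged size;
4. a channel-attention module that gates each of the F2 maps with a weight
   in (0, 1) before the flatten + softmax head.

ELU follows every convolutional block.  The two comparison networks reuse
the same layer implementations: TCNN is the convolutional pair + softmax on
raw windows; CNN-LSTM stacks two channel-wise LSTM layers before the three
convolutional stages.

Training is Adam on class-weighted cross-entropy over batches of 10
temporally ordered windows from a single trial, with validation stopping
(the returned weights minimize validation loss over the epoch budget).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import WindowSet
from .nn import (
    Adam,
    ChannelAttention,
    ChannelLSTM,
    ChannelMean,
    Dense,
    DepthwiseSpatialConv,
    DepthwiseTimeConv,
    ELU,
    Flatten,
    Layer,
    PointwiseConv,
    TemporalConv,
    softmax,
    weighted_cross_entropy,
)
from .preprocess import compute_class_weights

__all__ = [
    "MCSNetConfig",
    "TrainConfig",
    "MCSNet",
    "TCNN",
    "CNNLSTM",
    "build_model",
    "build_baseline_net",
    "classify_forward",
    "train_model",
    "TrainedModel",
    "predict_labels",
]

ABLATABLE_LAYERS = ("depthwise", "separable", "attention")


@dataclass(frozen=True)
class MCSNetConfig:
    """Architecture hyperparameters; defaults are the study's (D, F1, L) = (2, 12, 300)."""

    n_channels: int = 12
    window_len: int = 300
    lstm_hidden: int = 300
    f1: int = 12
    temporal_kernel: int = 65
    depth: int = 2
    separable_kernel: int = 15
    attention_reduction: int = 4
    n_classes: int = 4
    tie_symmetric_lstm: bool = True

    @property
    def f2(self) -> int:
        # the separable block preserves size, so its width equals D * F1
        return self.depth * self.f1

    def validate(self) -> None:
        if min(self.n_channels, self.window_len, self.lstm_hidden, self.f1,
               self.depth, self.n_classes, self.attention_reduction) < 1:
            raise ValueError("all architecture dimensions must be >= 1")
        if self.n_channels < 2:
            raise ValueError("need at least two sEMG channels")
        if self.tie_symmetric_lstm and self.n_channels % 2 != 0:
            raise ValueError("symmetric-pair weight tying requires an even channel count")
        for k in (self.temporal_kernel, self.separable_kernel):
            if k > self.lstm_hidden:
                raise ValueError(f"kernel {k} longer than feature length {self.lstm_hidden}")

    @classmethod
    def scaled(cls, **overrides) -> "MCSNetConfig":
        """A reduced configuration for desk-scale CPU experiments.

        Same topology, smaller widths: 100-sample windows, hidden 32, F1 = 4,
        D = 2 (F2 = 8), kernels 17/7.  Used by the scaled end-to-end studies.
        """
        base = dict(
            window_len=100, lstm_hidden=32, f1=4, temporal_kernel=17,
            depth=2, separable_kernel=7, attention_reduction=4,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam defaults, class-weighted cross-entropy,
    batches of 10 ordered windows, validation stopping."""

    epochs: int = 1000
    batch: int = 10
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be >= 1")


class _SequentialNet:
    """Shared plumbing for the three architectures."""

    arch: str = ""

    def __init__(self) -> None:
        self._layers: list[Layer] = []

    def parameters(self):
        return [p for layer in self._layers for p in layer.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match parameter list")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities, deterministic, in chunks."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out)


class MCSNet(_SequentialNet):
    """The four-block channel-synergy network (optionally with one block ablated).

    ``removed`` in {None, 'depthwise', 'separable', 'attention'} deletes one
    structural layer; shape reconciliation is parameter-free (removing the
    depthwise block inserts a plain channel-axis average; the other removals
    are pure pass-throughs).
    """

    arch = "MCSNet"

    def __init__(self, cfg: MCSNetConfig, rng: np.random.Generator | None = None,
                 removed: str | None = None):
        super().__init__()
        cfg.validate()
        if removed is not None and removed not in ABLATABLE_LAYERS:
            raise ValueError(f"unknown layer {removed!r}; ablatable: {ABLATABLE_LAYERS}")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.removed = removed
        C, H = cfg.n_channels, cfg.lstm_hidden
        self.lstm = ChannelLSTM(C, H, input_dim=1, tied=cfg.tie_symmetric_lstm, rng=rng)
        self.tconv = TemporalConv(cfg.f1, cfg.temporal_kernel, rng=rng)
        self.elu1 = ELU()
        if removed == "depthwise":
            self.spatial: Layer = ChannelMean()
            width = cfg.f1
        else:
            self.spatial = DepthwiseSpatialConv(cfg.f1, cfg.depth, C, rng=rng)
            width = cfg.f2
        self.elu2 = ELU()
        self.width = width
        if removed != "separable":
            self.sep_dw = DepthwiseTimeConv(width, cfg.separable_kernel, rng=rng)
            self.sep_pw = PointwiseConv(width, width, rng=rng)
            self.elu3 = ELU()
        else:
            self.sep_dw = self.sep_pw = self.elu3 = None
        if removed != "attention":
            self.attention = ChannelAttention(width, cfg.attention_reduction, rng=rng)
        else:
            self.attention = None
        self.flatten = Flatten()
        self.head = Dense(width * H, cfg.n_classes, rng=rng)
        self._layers = [l for l in (
            self.lstm, self.tconv, self.elu1, self.spatial, self.elu2,
            self.sep_dw, self.sep_pw, self.elu3, self.attention,
            self.flatten, self.head) if l is not None]

    # -- staged forward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, record: dict | None = None):
        if x.ndim == 2:
            x = x[None]
        f_temp = self.lstm.forward(x, train)                      # (B, C, H)
        f_conv = self.elu1.forward(self.tconv.forward(f_temp, train), train)  # (B, F1, C, H)
        f_dconv = self.spatial.forward(f_conv, train)             # (B, width, H)
        if self.removed != "depthwise":
            f_dconv = self.elu2.forward(f_dconv, train)
        if self.sep_dw is not None:
            f_sep = self.elu3.forward(
                self.sep_pw.forward(self.sep_dw.forward(f_dconv, train), train), train
            )
        else:
            f_sep = f_dconv
        if self.attention is not None:
            f_att = self.attention.forward(f_sep, train)
        else:
            f_att = f_sep
        logits = self.head.forward(self.flatten.forward(f_att, train), train)
        if record is not None:
            record["lstm"] = f_temp
            record["conv1"] = f_conv
            record["dconv"] = f_dconv[:, :, None, :]
            record["sepconv"] = f_sep[:, :, None, :]
            record["attended"] = f_att[:, :, None, :]
            if self.attention is not None:
                record["attention_weights"] = self.attention.last_weights
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.flatten.backward(self.head.backward(dlogits))
        if self.attention is not None:
            d = self.attention.backward(d)
        if self.sep_dw is not None:
            d = self.sep_dw.backward(self.sep_pw.backward(self.elu3.backward(d)))
        if self.removed != "depthwise":
            d = self.elu2.backward(d)
        d = self.spatial.backward(d)
        d = self.tconv.backward(self.elu1.backward(d))
        self.lstm.backward(d)

    def activations(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Per-stage feature maps (inference mode) for explainability analyses."""
        rec: dict[str, np.ndarray] = {}
        self.forward(x, train=False, record=rec)
        return rec

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-window attention weights, shape (B, width)."""
        if self.attention is None:
            raise ValueError("model has no attention layer (ablated)")
        self.forward(x, train=False)
        return self.attention.last_weights


class TCNN(_SequentialNet):
    """Two convolutional layers + softmax on raw windows (deep baseline)."""

    arch = "TCNN"

    def __init__(self, cfg: MCSNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        if cfg.temporal_kernel > cfg.window_len:
            raise ValueError("temporal kernel longer than the raw window")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.tconv = TemporalConv(cfg.f1, cfg.temporal_kernel, rng=rng)
        self.elu1 = ELU()
        self.spatial = DepthwiseSpatialConv(cfg.f1, cfg.depth, cfg.n_channels, rng=rng)
        self.elu2 = ELU()
        self.flatten = Flatten()
        self.head = Dense(cfg.f2 * cfg.window_len, cfg.n_classes, rng=rng)
        self._layers = [self.tconv, self.elu1, self.spatial, self.elu2, self.flatten, self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        h = self.elu1.forward(self.tconv.forward(x, train), train)
        h = self.elu2.forward(self.spatial.forward(h, train), train)
        return self.head.forward(self.flatten.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.flatten.backward(self.head.backward(dlogits))
        d = self.spatial.backward(self.elu2.backward(d))
        self.tconv.backward(self.elu1.backward(d))


class CNNLSTM(_SequentialNet):
    """Two stacked channel-wise LSTM layers + three convolutional stages + softmax."""

    arch = "CNN-LSTM"

    def __init__(self, cfg: MCSNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        C, H = cfg.n_channels, cfg.lstm_hidden
        tie = cfg.tie_symmetric_lstm
        self.lstm1 = ChannelLSTM(C, H, input_dim=1, tied=tie, return_sequences=True, rng=rng)
        self.lstm2 = ChannelLSTM(C, H, input_dim=H, tied=tie, rng=rng)
        self.tconv = TemporalConv(cfg.f1, cfg.temporal_kernel, rng=rng)
        self.elu1 = ELU()
        self.spatial = DepthwiseSpatialConv(cfg.f1, cfg.depth, C, rng=rng)
        self.elu2 = ELU()
        self.sep_dw = DepthwiseTimeConv(cfg.f2, cfg.separable_kernel, rng=rng)
        self.elu3 = ELU()
        self.flatten = Flatten()
        self.head = Dense(cfg.f2 * H, cfg.n_classes, rng=rng)
        self._layers = [self.lstm1, self.lstm2, self.tconv, self.elu1, self.spatial,
                        self.elu2, self.sep_dw, self.elu3, self.flatten, self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        h = self.lstm1.forward(x, train)          # (B, C, L, H)
        h = self.lstm2.forward(h, train)          # (B, C, H)
        h = self.elu1.forward(self.tconv.forward(h, train), train)
        h = self.elu2.forward(self.spatial.forward(h, train), train)
        h = self.elu3.forward(self.sep_dw.forward(h, train), train)
        return self.head.forward(self.flatten.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.flatten.backward(self.head.backward(dlogits))
        d = self.sep_dw.backward(self.elu3.backward(d))
        d = self.spatial.backward(self.elu2.backward(d))
        d = self.tconv.backward(self.elu1.backward(d))
        self.lstm1.backward(self.lstm2.backward(d))


_ARCHS = {"MCSNET": MCSNet, "TCNN": TCNN, "CNN-LSTM": CNNLSTM, "CNNLSTM": CNNLSTM}


def build_model(arch: str, cfg: MCSNetConfig, seed: int = 0, removed: str | None = None):
    """Construct an architecture by name with a seeded initialization."""
    key = arch.upper()
    if key not in _ARCHS:
        raise ValueError(f"unknown architecture {arch!r}; valid: MCSNet, TCNN, CNN-LSTM")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA]))
    cls = _ARCHS[key]
    if cls is MCSNet:
        return MCSNet(cfg, rng=rng, removed=removed)
    if removed is not None:
        raise ValueError("layer ablation applies to MCSNet only")
    return cls(cfg, rng=rng)


def build_baseline_net(kind: str, cfg: MCSNetConfig, seed: int = 0):
    """The two deep comparison networks: kind in {'TCNN', 'CNN-LSTM'}."""
    if kind.upper() not in ("TCNN", "CNN-LSTM", "CNNLSTM"):
        raise ValueError(f"unknown baseline network {kind!r}; valid: TCNN, CNN-LSTM")
    return build_model(kind, cfg, seed=seed)


def classify_forward(batch: np.ndarray, model: _SequentialNet) -> np.ndarray:
    """Class probabilities for a batch of windows; rows sum to 1."""
    return model.predict_proba(np.asarray(batch, dtype=float))


def predict_labels(model: _SequentialNet, ws: WindowSet, batch_size: int = 256) -> np.ndarray:
    return np.argmax(model.predict_proba(ws.windows, batch_size=batch_size), axis=1)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def _ordered_batches(ws: WindowSet, batch: int) -> list[np.ndarray]:
    """Chunks of `batch` consecutive windows from one trial each.

    Window order inside a chunk follows the trial's temporal order; the
    caller shuffles the chunk list between epochs.
    """
    chunks = []
    trials = ws.trial_ids.astype(str)
    for trial in sorted(set(trials)):
        idx = np.flatnonzero(trials == trial)
        idx = idx[np.argsort(ws.window_order[idx])]
        for i in range(0, len(idx), batch):
            chunks.append(idx[i : i + batch])
    return chunks


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reload and audit it."""

    model: _SequentialNet
    train_config: TrainConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1
    class_weights: np.ndarray | None = None

    @property
    def arch(self) -> str:
        return self.model.arch

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "arch": self.model.arch,
            "config": self.model.cfg.to_dict(),
            "removed": getattr(self.model, "removed", None),
            "train_config": dataclasses.asdict(self.train_config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "class_weights": None if self.class_weights is None else list(self.class_weights),
        }
        arrays = {f"param_{i}": w for i, w in enumerate(self.model.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = MCSNetConfig(**meta["config"])
        model = build_model(meta["arch"], cfg,
                            seed=meta["train_config"]["seed"], removed=meta["removed"])
        n = len([k for k in data.files if k.startswith("param_")])
        model.set_weights([data[f"param_{i}"] for i in range(n)])
        cw = meta["class_weights"]
        return TrainedModel(
            model=model,
            train_config=TrainConfig(**meta["train_config"]),
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            class_weights=None if cw is None else np.array(cw),
        )


def _eval_loss_acc(model, ws: WindowSet, weights: np.ndarray, batch_size: int = 256):
    losses, hits, wsum = 0.0, 0, 0.0
    for i in range(0, len(ws), batch_size):
        x, y = ws.windows[i : i + batch_size], ws.labels[i : i + batch_size]
        logits = model.forward(x, train=False)
        loss, _ = weighted_cross_entropy(logits, y, weights)
        wi = weights[y].sum()
        losses += loss * wi
        wsum += wi
        hits += int(np.sum(np.argmax(logits, axis=1) == y))
    return losses / wsum, hits / len(ws)


def train_model(
    model: _SequentialNet,
    train: WindowSet,
    val: WindowSet,
    tc: TrainConfig,
) -> TrainedModel:
    """Train with Adam on class-weighted cross-entropy, keeping the best-validation weights.

    Class weights come from the training labels only.  Batches are ``tc.batch``
    consecutive windows of one trial; the batch order is reshuffled every
    epoch from the seeded generator, so two runs with the same seed produce
    bit-identical histories and weights.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation window sets must be nonempty")
    cw = compute_class_weights(train.labels)
    n_classes = getattr(model, "cfg").n_classes
    weights = cw.as_array(n_classes)
    if set(train.labels) - set(val.labels):
        warnings.warn("validation set is missing some training classes", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0xB]))
    opt = Adam(model.parameters(), lr=tc.lr)
    chunks = _ordered_batches(train, tc.batch)
    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "val_acc": [], "train_acc": []
    }
    best_loss, best_epoch, best_weights = np.inf, -1, model.get_weights()
    for epoch in range(tc.epochs):
        order = rng.permutation(len(chunks))
        epoch_loss, epoch_w, epoch_hits = 0.0, 0.0, 0
        for ci in order:
            idx = chunks[ci]
            x, y = train.windows[idx], train.labels[idx]
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, dlogits = weighted_cross_entropy(logits, y, weights)
            model.backward(dlogits)
            opt.step()
            wi = weights[y].sum()
            epoch_loss += loss * wi
            epoch_w += wi
            epoch_hits += int(np.sum(np.argmax(logits, axis=1) == y))
        val_loss, val_acc = _eval_loss_acc(model, val, weights)
        history["train_loss"].append(epoch_loss / epoch_w)
        history["train_acc"].append(epoch_hits / len(train))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(
        model=model,
        train_config=tc,
        history=history,
        best_epoch=best_epoch,
        class_weights=weights,
    )
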