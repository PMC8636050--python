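"""Channel-synergy explainability: NMF contributions, flow tracing, attention agreement.

The analysis asks whether the network's internal structure reflects the
muscle synergies present in the data.  Three steps:

1. **Channel contribution.** Average the (rectified) class-conditional
   signal — raw windows or a layer's per-channel activations — into a
   ``channels x length`` matrix and factor it with non-negative matrix
   factorization (multiplicative updates, Frobenius objective).  Channels
   whose basis loading exceeds a fraction τ of the largest loading are the
   dominant contribution channels.

2. **Information-flow tracing.** Follow the dominant source channels through
   the learned weights: depthwise spatial filters that concentrate absolute
   weight mass on the dominant channels form the spatiotemporal flow set;
   the separable pointwise weights propagate that set one layer further.

3. **Attention agreement.** Compare the final flow set with the channels the
   attention module weights most highly (top quartile, averaged over an
   evaluation batch), as a Jaccard overlap in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import WindowSet
from .mcsnet import MCSNet

__all__ = [
    "SynergyDecomposition",
    "FlowTrace",
    "nmf",
    "channel_contribution_nmf",
    "layer_activation_nmf",
    "trace_information_flow",
    "jaccard",
]


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 for two empty sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class SynergyDecomposition:
    """Non-negative factorization of a channel-by-time activation matrix."""

    basis: np.ndarray  # (channels, k), non-negative
    activations: np.ndarray  # (k, length), non-negative
    dominant_channels: list[int] = field(default_factory=list)
    reconstruction_error: float = 0.0
    objective_history: list[float] = field(default_factory=list)


@dataclass
class FlowTrace:
    """Dominant-channel sets at each traced stage plus the agreement statistic."""

    source_channels: list[int]
    spatiotemporal_channels: list[int]
    separable_channels: list[int]
    attention_top: list[int]
    agreement: float


def nmf(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF minimizing ||X - WH||_F.

    The Frobenius objective is checked to be non-increasing at every update
    (a structural property of the multiplicative rules; a violation beyond
    numerical noise raises).  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative (rectify first)")
    m, n = X.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k={k} out of range for a {m}x{n} matrix")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = scale * rng.uniform(0.1, 1.0, size=(m, k))
    H = scale * rng.uniform(0.1, 1.0, size=(k, n))
    eps = 1e-12
    err_prev = np.linalg.norm(X - W @ H)
    history = [float(err_prev)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        err = np.linalg.norm(X - W @ H)
        if err > err_prev * (1 + 1e-10) + 1e-12:
            raise RuntimeError("NMF objective increased: multiplicative update broken")
        history.append(float(err))
        if err_prev - err < tol * max(err_prev, 1.0):
            break
        err_prev = err
    return W, H, history


def _dominant_from_basis(basis: np.ndarray, tau: float) -> list[int]:
    loading = basis.max(axis=1)
    top = loading.max()
    if top <= 0:
        return []
    dominant = np.flatnonzero(loading > tau * top)
    return [int(c) for c in dominant[np.argsort(-loading[dominant])]]


def channel_contribution_nmf(
    avg_activation: np.ndarray,
    k: int = 1,
    tau: float = 0.5,
    seed: int = 0,
    max_iter: int = 400,
) -> SynergyDecomposition:
    """Factor a class-averaged ``channels x length`` map; rank dominant channels.

    The input is rectified (absolute value) before factorization since sEMG
    and network activations are signed while NMF requires non-negativity.
    Dominant channels are those whose basis loading exceeds ``tau`` times the
    largest loading, ranked by loading.
    """
    X = np.abs(np.asarray(avg_activation, dtype=float))
    W, H, history = nmf(X, k, seed=seed, max_iter=max_iter)
    return SynergyDecomposition(
        basis=W,
        activations=H,
        dominant_channels=_dominant_from_basis(W, tau),
        reconstruction_error=history[-1],
        objective_history=history,
    )


def layer_activation_nmf(
    model: MCSNet,
    ws: WindowSet,
    layer: str = "lstm",
    movement: int | None = None,
    k: int = 1,
    tau: float = 0.5,
    seed: int = 0,
    batch_size: int = 256,
) -> SynergyDecomposition:
    """NMF of a layer's class-averaged per-channel activations.

    ``layer`` is 'input', 'lstm' (timing features, C x H) or 'conv1' (first
    convolution, collapsed over its F1 filter bank to C x H).  ``movement``
    restricts the average to one class; None averages everything.
    """
    if len(ws) == 0:
        raise ValueError("empty WindowSet")
    mask = np.ones(len(ws), dtype=bool) if movement is None else ws.labels == int(movement)
    if not mask.any():
        raise ValueError(f"no windows with label {movement}")
    idx = np.flatnonzero(mask)
    acc: np.ndarray | None = None
    for i in range(0, len(idx), batch_size):
        x = ws.windows[idx[i : i + batch_size]]
        if layer == "input":
            a = np.abs(x)
        else:
            rec = model.activations(x)
            if layer == "lstm":
                a = np.abs(rec["lstm"])  # (B, C, H)
            elif layer == "conv1":
                a = np.abs(rec["conv1"]).mean(axis=1)  # (B, F1, C, H) -> (B, C, H)
            else:
                raise ValueError(f"unknown layer {layer!r}; valid: input, lstm, conv1")
        part = a.sum(axis=0)
        acc = part if acc is None else acc + part
    avg = acc / len(idx)
    return channel_contribution_nmf(avg, k=k, tau=tau, seed=seed)


def trace_information_flow(
    model: MCSNet,
    dominant: list[int] | set[int],
    ws: WindowSet | None = None,
    theta: str | float = "median",
    batch_size: int = 256,
) -> FlowTrace:
    """Trace the dominant sEMG channels through the learned weights.

    For each depthwise spatial filter, compute the fraction of its absolute
    weight mass on the dominant source channels; filters above the median
    fraction (or above an explicit ``theta``) form the spatiotemporal flow
    set.  The separable pointwise weights propagate that mass one layer on.
    ``attention_top`` is the top quartile of attention weights averaged over
    the evaluation windows; agreement is the Jaccard overlap of the final
    flow set with it.
    """
    dominant = sorted(int(c) for c in dominant)
    if getattr(model, "removed", None) == "depthwise" or not hasattr(model.spatial, "W"):
        raise ValueError("model lacks a depthwise spatial layer (ablated)")
    if model.sep_pw is None:
        raise ValueError("model lacks a separable layer (ablated)")
    if model.attention is None:
        raise ValueError("model lacks an attention layer (ablated)")

    W = np.abs(model.spatial.W.value)  # (F1, D, C)
    mass = W.reshape(-1, W.shape[-1])  # (F2, C): flat index f*D + d
    frac = mass[:, dominant].sum(axis=1) / np.maximum(mass.sum(axis=1), 1e-12)
    cut = float(np.median(frac)) if theta == "median" else float(theta)
    flow_spatio = [int(j) for j in np.flatnonzero(frac > cut)]

    Wp = np.abs(model.sep_pw.W.value)  # (F2_out, F2_in)
    pw_frac = Wp[:, flow_spatio].sum(axis=1) / np.maximum(Wp.sum(axis=1), 1e-12)
    pw_cut = float(np.median(pw_frac)) if theta == "median" else float(theta)
    flow_sep = [int(j) for j in np.flatnonzero(pw_frac > pw_cut)]

    if ws is None or len(ws) == 0:
        raise ValueError("an evaluation WindowSet is required for the attention comparison")
    w_sum, n = 0.0, 0
    for i in range(0, len(ws), batch_size):
        w_sum = w_sum + model.attention_weights(ws.windows[i : i + batch_size]).sum(axis=0)
        n += min(batch_size, len(ws) - i)
    attn = w_sum / n
    q3 = np.quantile(attn, 0.75)
    attention_top = [int(j) for j in np.flatnonzero(attn >= q3)]

    return FlowTrace(
        source_channels=dominant,
        spatiotemporal_channels=flow_spatio,
        separable_channels=flow_sep,
        attention_top=attention_top,
        agreement=jaccard(flow_sep, attention_top),
    )
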