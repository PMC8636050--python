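"""Minimal NumPy neural-network engine with hand-derived gradients.

Implements exactly the layer zoo the movement-prediction networks need:
channel-wise LSTMs with optional symmetric-pair weight sharing, a temporal
convolution bank, depthwise spatial convolution, depthwise-separable
temporal convolution, a squeeze/excite-style channel-attention module,
dense + softmax classification, and an Adam optimizer.

Every layer caches its forward intermediates when ``train=True`` and exposes
``backward(dout)`` returning the input gradient while accumulating parameter
gradients in-place.  All math is float64; the backward passes are validated
against central-difference numerical gradients in the test suite.

Internal tensor layout: feature maps are carried as ``(B, F, L)`` — the
singleton spatial axis of the ``(F, 1, L)`` presentation shape is implicit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "ChannelLSTM",
    "TemporalConv",
    "DepthwiseSpatialConv",
    "ChannelMean",
    "DepthwiseTimeConv",
    "PointwiseConv",
    "ELU",
    "ChannelAttention",
    "Flatten",
    "Dense",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ChannelLSTM(Layer):
    """One LSTM per sEMG channel, run over the window's sample sequence.

    Channel ``k``'s scalar (or vector) series is consumed by LSTM unit ``k``;
    with ``tied=True`` (C even) units ``k`` and ``k + C/2`` share storage, so
    the left/right symmetric muscle pair is processed by identical weights by
    construction.  Returns the final hidden state per channel ``(B, C, H)``,
    or the full sequence ``(B, C, L, H)`` with ``return_sequences``.
    """

    def __init__(
        self,
        n_channels: int,
        hidden: int,
        input_dim: int = 1,
        tied: bool = True,
        return_sequences: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if tied and n_channels % 2 != 0:
            raise ValueError("symmetric-pair weight tying requires an even channel count")
        rng = rng or np.random.default_rng(0)
        self.C = n_channels
        self.H = hidden
        self.Din = input_dim
        self.tied = tied
        self.return_sequences = return_sequences
        self.G = n_channels // 2 if tied else n_channels  # distinct units
        self.S = n_channels // self.G  # channels (slots) per unit
        H, G, Din = hidden, self.G, input_dim
        wx = np.stack([
            np.concatenate([glorot(rng, (Din, H), Din, H) for _ in range(4)], axis=1)
            for _ in range(G)
        ])
        wh = np.stack([
            np.concatenate([orthogonal(rng, H) for _ in range(4)], axis=1) for _ in range(G)
        ])
        b = np.zeros((G, 4 * H))
        b[:, H : 2 * H] = 1.0  # forget-gate bias: standard trainability default
        self.Wx = Param(wx, "lstm.Wx")
        self.Wh = Param(wh, "lstm.Wh")
        self.b = Param(b, "lstm.b")

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def unit_for_channel(self, k: int) -> int:
        """Index of the weight bank serving channel ``k`` (pairs share one)."""
        return k % self.G

    def _rearrange(self, x: np.ndarray) -> np.ndarray:
        # (B, C, L, Din) -> (G, S*B, L, Din); channel k maps to unit k % G, slot k // G,
        # so the symmetric pair (k, k + C/2) lands in slots 0 and 1 of one unit.
        B, C, L, Din = x.shape
        xc = x.transpose(1, 0, 2, 3)  # (C, B, L, Din), c = slot * G + unit
        xg = xc.reshape(self.S, self.G, B, L, Din).transpose(1, 0, 2, 3, 4)
        return xg.reshape(self.G, self.S * B, L, Din)

    def _restore(self, yg: np.ndarray, B: int) -> np.ndarray:
        # inverse of _rearrange for arbitrary trailing feature dims
        tail = yg.shape[2:]
        y = yg.reshape(self.G, self.S, B, *tail)
        y = y.transpose(1, 0, 2, *range(3, 3 + len(tail)))
        y = y.reshape(self.G * self.S, B, *tail)
        return np.moveaxis(y, 1, 0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:  # scalar series per channel
            x = x[..., None]
        B, C, L, Din = x.shape
        if C != self.C or Din != self.Din:
            raise ValueError(f"input shape {x.shape} incompatible with C={self.C}, Din={self.Din}")
        G, S, H = self.G, self.S, self.H
        xg = np.ascontiguousarray(self._rearrange(x))
        h = np.zeros((G, S * B, H))
        c = np.zeros((G, S * B, H))
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        cache = [] if train else None
        hs = np.empty((L, G, S * B, H)) if (train or self.return_sequences) else None
        for t in range(L):
            z = xg[:, :, t, :] @ Wx + h @ Wh + b[:, None, :]
            i = _sigmoid(z[..., :H])
            f = _sigmoid(z[..., H : 2 * H])
            g = np.tanh(z[..., 2 * H : 3 * H])
            o = _sigmoid(z[..., 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if hs is not None:
                hs[t] = h
            if train:
                cache.append((i, f, g, o, c_prev, tc))
        self._cache = (xg, hs, cache, B) if train else None
        if self.return_sequences:
            return self._restore(hs.transpose(1, 2, 0, 3), B)  # (B, C, L, H)
        return self._restore(h, B)  # (B, C, H)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xg, hs, cache, B = self._cache
        G, S, H, L = self.G, self.S, self.H, xg.shape[2]
        if self.return_sequences:
            # (B, C, L, H) -> (L, G, S*B, H)
            dseq = self._rearrange(dout).transpose(2, 0, 1, 3)
            dh_final = None
        else:
            dseq = None
            dh_final = self._rearrange(dout[:, :, None, :])[:, :, 0, :]
        dxg = np.empty_like(xg)
        dWx, dWh, db = self.Wx.grad, self.Wh.grad, self.b.grad
        Wx, Wh = self.Wx.value, self.Wh.value
        dh_next = np.zeros((G, S * B, H))
        dc_next = np.zeros((G, S * B, H))
        for t in range(L - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dh_next.copy()
            if dseq is not None:
                dh += dseq[t]
            elif t == L - 1:
                dh += dh_final
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=-1,
            )
            db += dz.sum(axis=1)
            xt = xg[:, :, t, :]
            dWx += xt.transpose(0, 2, 1) @ dz
            dxg[:, :, t, :] = dz @ Wx.transpose(0, 2, 1)
            h_prev = hs[t - 1] if t > 0 else np.zeros((G, S * B, H))
            dWh += h_prev.transpose(0, 2, 1) @ dz
            dh_next = dz @ Wh.transpose(0, 2, 1)
        dx = self._restore(dxg, B)  # (B, C, L, Din)
        return dx[..., 0] if self.Din == 1 else dx


def _same_pad_windows(x: np.ndarray, K: int) -> np.ndarray:
    """Symmetric zero padding then length-K sliding windows along the last axis."""
    pad = K // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)])
    return np.lib.stride_tricks.sliding_window_view(xp, K, axis=-1)


def _overlap_add(g: np.ndarray, L: int, K: int) -> np.ndarray:
    """Adjoint of `_same_pad_windows`: scatter window gradients back to the signal."""
    pad = K // 2
    dxp = np.zeros(g.shape[:-2] + (L + 2 * pad,))
    for k in range(K):
        dxp[..., k : k + L] += g[..., k]
    return dxp[..., pad : pad + L]


class TemporalConv(Layer):
    """F1 filters of shape (1, K), same-padded along the sample axis.

    (B, C, L) -> (B, F1, C, L); each filter sees every channel's series with
    the same one-dimensional kernel (the 2-D kernel's channel extent is 1).
    """

    def __init__(self, f1: int, kernel: int, rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("temporal kernel must be odd for exact same padding")
        rng = rng or np.random.default_rng(0)
        self.F1, self.K = f1, kernel
        self.W = Param(glorot(rng, (f1, kernel), kernel, f1), "tconv.W")
        self.b = Param(np.zeros(f1), "tconv.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if self.K > L:
            raise ValueError(f"kernel {self.K} longer than sequence {L}")
        win = _same_pad_windows(x, self.K)  # (B, C, L, K) view
        out = win @ self.W.value.T  # (B, C, L, F1)
        if train:
            self._cache = (win, L)
        return out.transpose(0, 3, 1, 2) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, L = self._cache
        dt = dout.transpose(0, 2, 3, 1)  # (B, C, L, F1)
        self.W.grad += np.tensordot(dt, win, axes=([0, 1, 2], [0, 1, 2]))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        g = dt @ self.W.value  # (B, C, L, K)
        return _overlap_add(g, L, self.K)


class DepthwiseSpatialConv(Layer):
    """Depthwise conv of size (C, 1) with depth multiplier D.

    Collapses the electrode axis: (B, F1, C, L) -> (B, D*F1, L); spatial
    filter (f, d) is a learned weighting over the C channels of temporal
    feature map f, i.e. a learned spatial (synergy-mixing) pattern.
    """

    def __init__(self, f1: int, depth: int, n_channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.F1, self.D, self.C = f1, depth, n_channels
        self.W = Param(glorot(rng, (f1, depth, n_channels), n_channels, depth), "dwconv.W")
        self.b = Param(np.zeros(f1 * depth), "dwconv.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B = x.shape[0]
        out = np.einsum("bfcl,fdc->bfdl", x, self.W.value, optimize=True)
        if train:
            self._cache = x
        return out.reshape(B, self.F1 * self.D, -1) + self.b.value[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        B, _, L = dout.shape
        r = dout.reshape(B, self.F1, self.D, L)
        self.W.grad += np.einsum("bfcl,bfdl->fdc", x, r, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2))
        return np.einsum("bfdl,fdc->bfcl", r, self.W.value, optimize=True)


class ChannelMean(Layer):
    """Parameter-free channel-axis average: the depthwise-ablation shim.

    (B, F1, C, L) -> (B, F1, L), so downstream shapes survive the removal of
    the learned spatial filters without introducing new parameters.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._C = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None, :], self._C, axis=2) / self._C


class DepthwiseTimeConv(Layer):
    """Per-feature-map (1, K) depthwise convolution, same-padded; no bias.

    The first stage of the separable block: each spatiotemporal feature map
    is filtered independently along time.
    """

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("separable kernel must be odd for exact same padding")
        rng = rng or np.random.default_rng(0)
        self.F, self.K = n_maps, kernel
        self.W = Param(glorot(rng, (n_maps, kernel), kernel, 1), "sepdw.W")

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        L = x.shape[-1]
        if self.K > L:
            raise ValueError(f"kernel {self.K} longer than sequence {L}")
        win = _same_pad_windows(x, self.K)  # (B, F, L, K)
        if train:
            self._cache = (win, L)
        return np.einsum("bflk,fk->bfl", win, self.W.value, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, L = self._cache
        self.W.grad += np.einsum("bflk,bfl->fk", win, dout, optimize=True)
        g = np.einsum("bfl,fk->bflk", dout, self.W.value, optimize=True)
        return _overlap_add(g, L, self.K)


class PointwiseConv(Layer):
    """(1, 1) convolutions mixing feature maps: (B, F_in, L) -> (B, F_out, L)."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot(rng, (f_out, f_in), f_in, f_out), "seppw.W")
        self.b = Param(np.zeros(f_out), "seppw.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return np.einsum("bfl,gf->bgl", x, self.W.value, optimize=True) + self.b.value[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += np.einsum("bgl,bfl->gf", dout, x, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2))
        return np.einsum("bgl,gf->bfl", dout, self.W.value, optimize=True)


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        if train:
            self._cache = (x > 0, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        return dout * np.where(pos, 1.0, out + 1.0)


class ChannelAttention(Layer):
    """Squeeze/excite-style gating over spatiotemporal feature maps.

    Average- and max-pool each of the F maps over its spatial extent, push
    both pooled vectors through a shared two-layer perceptron (hidden F/r,
    ReLU), add, squash with a sigmoid, and rescale the maps by the resulting
    per-map weight in (0, 1).
    """

    def __init__(self, n_maps: int, reduction: int, rng: np.random.Generator | None = None):
        if n_maps % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide feature count {n_maps}")
        rng = rng or np.random.default_rng(0)
        hidden = n_maps // reduction
        self.F = n_maps
        self.W1 = Param(glorot(rng, (n_maps, hidden), n_maps, hidden), "attn.W1")
        self.b1 = Param(np.zeros(hidden), "attn.b1")
        self.W2 = Param(glorot(rng, (hidden, n_maps), hidden, n_maps), "attn.W2")
        self.b2 = Param(np.zeros(n_maps), "attn.b2")
        self.last_weights: np.ndarray | None = None  # (B, F), for inspection

    def params(self) -> list[Param]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _mlp(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(v @ self.W1.value + self.b1.value, 0.0)
        return h, h @ self.W2.value + self.b2.value

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        avg = x.mean(axis=2)
        amax = x.argmax(axis=2)
        mx = np.take_along_axis(x, amax[:, :, None], axis=2)[:, :, 0]
        ha, sa = self._mlp(avg)
        hm, sm = self._mlp(mx)
        w = _sigmoid(sa + sm)
        self.last_weights = w
        if train:
            self._cache = (x, w, avg, mx, ha, hm, amax)
        return x * w[:, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, w, avg, mx, ha, hm, amax = self._cache
        L = x.shape[2]
        dx = dout * w[:, :, None]
        dw = (dout * x).sum(axis=2)
        ds = dw * w * (1.0 - w)
        for v, h, pool in ((avg, ha, "avg"), (mx, hm, "max")):
            dh = ds @ self.W2.value.T
            self.W2.grad += h.T @ ds
            self.b2.grad += ds.sum(axis=0)
            dh = dh * (h > 0)
            self.W1.grad += v.T @ dh
            self.b1.grad += dh.sum(axis=0)
            dv = dh @ self.W1.value.T
            if pool == "avg":
                dx += dv[:, :, None] / L
            else:
                scatter = np.zeros_like(x)
                np.put_along_axis(scatter, amax[:, :, None], dv[:, :, None], axis=2)
                dx += scatter
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out), "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Class-weighted categorical cross-entropy and its logit gradient.

    Loss = sum_i w_{y_i} * (-log p_i[y_i]) / sum_i w_{y_i} — with all weights
    equal it reduces exactly to the unweighted mean.
    """
    B, N = logits.shape
    p = softmax(logits)
    wi = np.ones(B) if class_weights is None else np.asarray(class_weights)[labels]
    logp = np.log(p[np.arange(B), labels] + 1e-300)
    total_w = wi.sum()
    loss = float(-(wi * logp).sum() / total_w)
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (wi / total_w)[:, None]
    return loss, dlogits


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
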