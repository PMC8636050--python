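"""Layer-level behavior and analytic-vs-numerical gradient agreement."""

import numpy as np
import pytest

from synergynet import MCSNetConfig, build_model
from synergynet.nn import (
    ChannelAttention,
    ChannelLSTM,
    DepthwiseSpatialConv,
    DepthwiseTimeConv,
    ELU,
    PointwiseConv,
    TemporalConv,
    weighted_cross_entropy,
)

TINY = MCSNetConfig(
    n_channels=2, window_len=16, lstm_hidden=8, f1=2, temporal_kernel=5,
    depth=1, separable_kernel=3, attention_reduction=2, n_classes=4,
)


def numerical_gradient(f, param, indices, eps=1e-6):
    out = {}
    flat = param.value.ravel()
    for i in indices:
        orig = flat[i]
        flat[i] = orig + eps
        lp = f()
        flat[i] = orig - eps
        lm = f()
        flat[i] = orig
        out[i] = (lp - lm) / (2 * eps)
    return out


@pytest.mark.parametrize("arch", ["MCSNet", "TCNN", "CNN-LSTM"])
def test_analytic_gradients_match_numerical(arch):
    """Central differences vs backprop on a tiny configuration, 1e-4 relative."""
    model = build_model(arch, TINY, seed=1)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 2, 16))
    y = np.array([0, 1, 2])
    w = np.array([1.0, 2.0, 1.5, 1.0])

    for p in model.parameters():
        p.grad[...] = 0.0
    loss, dlogits = weighted_cross_entropy(model.forward(x, train=True), y, w)
    model.backward(dlogits)

    def f():
        return weighted_cross_entropy(model.forward(x, train=False), y, w)[0]

    rng_idx = np.random.default_rng(7)
    for p in model.parameters():
        idx = rng_idx.choice(p.value.size, size=min(12, p.value.size), replace=False)
        num = numerical_gradient(f, p, idx)
        for i, g_num in num.items():
            g_ana = p.grad.ravel()[i]
            denom = max(abs(g_num), abs(g_ana), 1e-6)
            assert abs(g_num - g_ana) / denom < 1e-4, p.name


class TestChannelLSTM:
    def test_output_shape_contract(self):
        lstm = ChannelLSTM(12, 300, rng=np.random.default_rng(0))
        out = lstm.forward(np.random.default_rng(1).standard_normal((2, 12, 300)))
        assert out.shape == (2, 12, 300)

    def test_tied_pairs_share_storage_and_stay_equal_after_updates(self):
        lstm = ChannelLSTM(4, 6, tied=True, rng=np.random.default_rng(0))
        assert lstm.unit_for_channel(0) == lstm.unit_for_channel(2)
        assert lstm.unit_for_channel(1) == lstm.unit_for_channel(3)
        x = np.random.default_rng(1).standard_normal((3, 4, 10))
        out = lstm.forward(x, train=True)
        lstm.backward(np.ones_like(out))
        for p in lstm.params():
            p.value -= 0.01 * p.grad  # a gradient step
        # shared storage: the pair is the same weight bank, trivially equal
        np.testing.assert_array_equal(
            lstm.Wh.value[lstm.unit_for_channel(0)], lstm.Wh.value[lstm.unit_for_channel(2)]
        )

    def test_symmetric_pair_swap_equivariance(self):
        """Swapping inputs k <-> k+C/2 swaps output rows exactly (shared weights)."""
        lstm = ChannelLSTM(6, 5, tied=True, rng=np.random.default_rng(0))
        x = np.random.default_rng(2).standard_normal((2, 6, 12))
        perm = [3, 1, 2, 0, 4, 5]  # swap channels 0 and 3 (= 0 + C/2)
        out = lstm.forward(x)
        out_swapped = lstm.forward(x[:, perm, :])
        np.testing.assert_array_equal(out[:, perm, :], out_swapped)

    def test_odd_channels_with_tying_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ChannelLSTM(5, 4, tied=True)

    def test_return_sequences_shape(self):
        lstm = ChannelLSTM(4, 7, tied=False, return_sequences=True,
                           rng=np.random.default_rng(0))
        out = lstm.forward(np.zeros((2, 4, 9)))
        assert out.shape == (2, 4, 9, 7)


class TestConvBlocks:
    def test_zero_input_yields_elu_of_bias(self):
        rng = np.random.default_rng(0)
        conv = TemporalConv(3, 5, rng=rng)
        conv.b.value[:] = [0.5, -0.5, 0.0]
        elu = ELU()
        out = elu.forward(conv.forward(np.zeros((1, 2, 10))))
        expected = np.where(conv.b.value > 0, conv.b.value, np.expm1(conv.b.value))
        for f in range(3):
            np.testing.assert_allclose(out[0, f], expected[f], atol=1e-12)

    def test_depthwise_time_conv_is_per_channel_local(self):
        """Zeroing input channel j changes only channel j of the depthwise output."""
        rng = np.random.default_rng(1)
        conv = DepthwiseTimeConv(4, 3, rng=rng)
        x = rng.standard_normal((2, 4, 20))
        base = conv.forward(x)
        x2 = x.copy()
        x2[:, 1, :] = 0.0
        out = conv.forward(x2)
        np.testing.assert_array_equal(np.delete(out, 1, axis=1), np.delete(base, 1, axis=1))
        assert not np.allclose(out[:, 1], base[:, 1])

    def test_separable_identity_construction(self):
        """Delta depthwise kernels + identity pointwise reduce to ELU(input)."""
        rng = np.random.default_rng(2)
        dw = DepthwiseTimeConv(3, 5, rng=rng)
        pw = PointwiseConv(3, 3, rng=rng)
        dw.W.value[:] = 0.0
        dw.W.value[:, 2] = 1.0  # centered delta
        pw.W.value[:] = np.eye(3)
        pw.b.value[:] = 0.0
        elu = ELU()
        x = rng.standard_normal((2, 3, 12))
        out = elu.forward(pw.forward(dw.forward(x)))
        np.testing.assert_allclose(out, np.where(x > 0, x, np.expm1(x)), atol=1e-12)

    def test_kernel_longer_than_sequence_rejected(self):
        conv = TemporalConv(2, 9, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="longer"):
            conv.forward(np.zeros((1, 2, 5)))


class TestChannelAttention:
    def test_zero_input_gives_identical_weights_across_channels(self):
        att = ChannelAttention(8, 2, rng=np.random.default_rng(0))
        att.forward(np.zeros((3, 8, 10)))
        w = att.last_weights
        np.testing.assert_allclose(w, np.broadcast_to(w[:, :1], w.shape), atol=1e-12)

    def test_weights_strictly_in_unit_interval(self):
        att = ChannelAttention(8, 2, rng=np.random.default_rng(0))
        att.forward(10 * np.random.default_rng(1).standard_normal((4, 8, 16)))
        assert np.all(att.last_weights > 0) and np.all(att.last_weights < 1)

    def test_scaling_one_channel_perturbs_only_its_pooled_inputs(self):
        """Pooling is per-channel: scaling channel j leaves other pools unchanged."""
        rng = np.random.default_rng(2)
        att = ChannelAttention(4, 2, rng=rng)
        x = np.abs(rng.standard_normal((2, 4, 12))) + 0.1  # positive-valued map
        att.forward(x)
        w0 = att.last_weights.copy()
        x2 = x.copy()
        x2[:, 1, :] *= 50.0
        att.forward(x2)
        w1 = att.last_weights
        assert not np.allclose(w0[:, 1], w1[:, 1])
        # other channels' pooled statistics are untouched by construction
        np.testing.assert_array_equal(x.mean(axis=2)[:, [0, 2, 3]],
                                      x2.mean(axis=2)[:, [0, 2, 3]])

    def test_reduction_must_divide_width(self):
        with pytest.raises(ValueError, match="divide"):
            ChannelAttention(6, 4)


class TestSpatialConv:
    def test_parameter_shapes(self):
        conv = DepthwiseSpatialConv(12, 2, 12, rng=np.random.default_rng(0))
        assert conv.W.value.shape == (12, 2, 12)
        out = conv.forward(np.zeros((1, 12, 12, 7)))
        assert out.shape == (1, 24, 7)


def test_weighted_loss_with_equal_weights_is_unweighted():
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((6, 4))
    y = np.array([0, 1, 2, 3, 0, 1])
    l_w, d_w = weighted_cross_entropy(logits, y, np.ones(4))
    l_u, d_u = weighted_cross_entropy(logits, y, None)
    assert l_w == pytest.approx(l_u, rel=1e-12)
    np.testing.assert_allclose(d_w, d_u, atol=1e-15)
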