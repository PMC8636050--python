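"""Architecture contracts, training determinism, checkpointing."""

import numpy as np
import pytest

from synergynet import (
    MCSNetConfig,
    TrainConfig,
    TrainedModel,
    build_baseline_net,
    build_model,
    classify_forward,
    train_model,
)

TINY = MCSNetConfig(
    n_channels=2, window_len=16, lstm_hidden=8, f1=2, temporal_kernel=5,
    depth=1, separable_kernel=3, attention_reduction=2, n_classes=4,
)


class TestShapesAndCounts:
    def test_default_shape_chain(self):
        """[12x300] -> [12x300] -> [12x12x300] -> [24x1x300] x3 -> [4]."""
        cfg = MCSNetConfig()
        model = build_model("MCSNet", cfg, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 12, 300))
        rec = {}
        logits = model.forward(x, record=rec)
        assert rec["lstm"].shape == (2, 12, 300)
        assert rec["conv1"].shape == (2, 12, 12, 300)
        assert rec["dconv"].shape == (2, 24, 1, 300)
        assert rec["sepconv"].shape == (2, 24, 1, 300)
        assert rec["attended"].shape == (2, 24, 1, 300)
        assert logits.shape == (2, 4)

    def test_conv_block_parameter_count_formula(self):
        """F1*K + F1 temporal weights/biases plus D*F1*C + D*F1 depthwise ones."""
        cfg = MCSNetConfig()
        model = build_model("MCSNet", cfg, seed=0)
        n_temporal = sum(p.value.size for p in model.tconv.params())
        n_spatial = sum(p.value.size for p in model.spatial.params())
        assert n_temporal == cfg.f1 * cfg.temporal_kernel + cfg.f1 == 780 + 12
        assert n_spatial == cfg.depth * cfg.f1 * cfg.n_channels + cfg.depth * cfg.f1
        assert n_temporal + n_spatial == 1104

    def test_cnnlstm_has_more_parameters_than_tcnn(self):
        tcnn = build_baseline_net("TCNN", TINY, seed=0)
        cnnlstm = build_baseline_net("CNN-LSTM", TINY, seed=0)
        assert cnnlstm.param_count() > tcnn.param_count()

    def test_f2_is_depth_times_f1(self):
        assert MCSNetConfig().f2 == 24
        assert MCSNetConfig.scaled().f2 == 8

    def test_config_validation_errors(self):
        with pytest.raises(ValueError, match="even"):
            MCSNetConfig(n_channels=3).validate()
        with pytest.raises(ValueError, match="kernel"):
            MCSNetConfig(lstm_hidden=50).validate()
        with pytest.raises(ValueError, match="unknown"):
            build_model("MCSNet", TINY, removed="dropout")
        with pytest.raises(ValueError, match="architecture"):
            build_model("ResNet", TINY)
        with pytest.raises(ValueError, match="baseline"):
            build_baseline_net("VGG", TINY)


class TestForwardContracts:
    @pytest.mark.parametrize("arch", ["MCSNet", "TCNN", "CNN-LSTM"])
    def test_softmax_rows_sum_to_one(self, arch):
        model = build_model(arch, TINY, seed=0)
        x = np.random.default_rng(1).standard_normal((10, 2, 16))
        proba = classify_forward(x, model)
        assert proba.shape == (10, 4)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_duplicated_inputs_give_identical_outputs(self):
        model = build_model("MCSNet", TINY, seed=0)
        x = np.random.default_rng(2).standard_normal((1, 2, 16))
        batch = np.concatenate([x, x, x])
        proba = classify_forward(batch, model)
        np.testing.assert_array_equal(proba[0], proba[1])
        np.testing.assert_array_equal(proba[0], proba[2])

    def test_argmax_of_probabilities_matches_logits(self):
        model = build_model("MCSNet", TINY, seed=0)
        x = np.random.default_rng(3).standard_normal((6, 2, 16))
        logits = model.forward(x)
        proba = classify_forward(x, model)
        np.testing.assert_array_equal(np.argmax(proba, 1), np.argmax(logits, 1))

    def test_attention_weights_in_open_unit_interval(self):
        model = build_model("MCSNet", TINY, seed=0)
        x = np.random.default_rng(4).standard_normal((5, 2, 16))
        w = model.attention_weights(x)
        assert w.shape == (5, TINY.f2)
        assert np.all(w > 0) and np.all(w < 1)


def _tiny_windows(seed, n_trials=4, per_trial=6, C=2, L=16):
    """Synthetic windows with class-dependent channel amplitude."""
    from synergynet.io import WindowSet

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


class TestTraining:
    def test_same_seed_reproduces_weights_and_history(self):
        train, val = _tiny_windows(0), _tiny_windows(1)
        tc = TrainConfig(epochs=3, batch=4, seed=5)
        runs = []
        for _ in range(2):
            tm = train_model(build_model("MCSNet", TINY, seed=5), train, val, tc)
            runs.append(tm)
        assert runs[0].history == runs[1].history
        for a, b in zip(runs[0].model.get_weights(), runs[1].model.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_best_epoch_attains_minimum_validation_loss(self):
        train, val = _tiny_windows(0), _tiny_windows(1)
        tm = train_model(build_model("MCSNet", TINY, seed=0), train, val,
                         TrainConfig(epochs=5, batch=4, seed=0))
        assert tm.best_epoch == int(np.argmin(tm.history["val_loss"]))

    def test_tied_lstm_pairs_remain_equal_through_training(self):
        train, val = _tiny_windows(0), _tiny_windows(1)
        tm = train_model(build_model("MCSNet", TINY, seed=0), train, val,
                         TrainConfig(epochs=2, batch=4, seed=0))
        lstm = tm.model.lstm
        # tied pairs share a weight bank; equality is structural
        assert lstm.unit_for_channel(0) == lstm.unit_for_channel(1)

    def test_missing_validation_class_warns(self):
        train = _tiny_windows(0)
        val = _tiny_windows(1)
        val = val.subset(val.labels == 0)
        with pytest.warns(UserWarning, match="missing"):
            train_model(build_model("MCSNet", TINY, seed=0), train, val,
                        TrainConfig(epochs=1, batch=4, seed=0))

    def test_empty_sets_rejected(self):
        train = _tiny_windows(0)
        with pytest.raises(ValueError, match="nonempty"):
            train_model(build_model("MCSNet", TINY, seed=0), train,
                        train.subset(np.zeros(len(train), dtype=bool)),
                        TrainConfig(epochs=1, batch=4, seed=0))


@pytest.mark.parametrize("arch", ["MCSNet", "TCNN", "CNN-LSTM"])
def test_checkpoint_roundtrip_bit_identical_inference(arch, tmp_path):
    train, val = _tiny_windows(0), _tiny_windows(1)
    tm = train_model(build_model(arch, TINY, seed=2), train, val,
                     TrainConfig(epochs=2, batch=4, seed=2))
    path = tmp_path / "model.npz"
    tm.save(path)
    back = TrainedModel.load(path)
    x = np.random.default_rng(9).standard_normal((4, 2, 16))
    np.testing.assert_array_equal(back.model.forward(x), tm.model.forward(x))
    assert back.best_epoch == tm.best_epoch
    assert back.history == tm.history


class TestAblatedVariants:
    @pytest.mark.parametrize("removed,width", [
        ("depthwise", TINY.f1), ("separable", TINY.f2), ("attention", TINY.f2),
    ])
    def test_removal_reconciles_shapes(self, removed, width):
        model = build_model("MCSNet", TINY, seed=0, removed=removed)
        x = np.random.default_rng(0).standard_normal((3, 2, 16))
        assert model.forward(x).shape == (3, 4)
        assert model.width == width

    def test_removed_layer_has_no_parameters_substituted(self):
        full = build_model("MCSNet", TINY, seed=0)
        no_dw = build_model("MCSNet", TINY, seed=0, removed="depthwise")
        spatial_params = sum(p.value.size for p in full.spatial.params())
        assert no_dw.param_count() < full.param_count()
        assert not no_dw.spatial.params()  # the channel-average shim is parameter-free
        assert spatial_params > 0
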