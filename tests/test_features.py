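"""Handcrafted features against brute-force oracles; baseline configuration."""

import numpy as np
import pytest

from synergynet import (
    FilterSpec,
    build_feature_matrix,
    configure_baseline,
    make_classifier,
    psd_mean,
    time_domain_features,
)
from synergynet.features import BASELINE_NAMES, ar_features, feature_names
from synergynet.preprocess import compute_class_weights


def brute_force_tdf(x):
    """Independent loop implementation of MAV / WL / ZC."""
    mav = sum(abs(v) for v in x) / len(x)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    zc = sum(
        1
        for i in range(len(x) - 1)
        if (x[i] > 0 and x[i + 1] < 0) or (x[i] < 0 and x[i + 1] > 0)
    )
    return mav, wl, zc


@pytest.mark.parametrize(
    "x,expected",
    [
        ([1.0, -1.0, 2.0, -2.0], (1.5, 9.0, 3)),
        ([3.0, 3.0, 3.0], (3.0, 0.0, 0)),
        ([-0.5, -0.5], (0.5, 0.0, 0)),
    ],
)
def test_time_domain_hand_examples(x, expected):
    assert time_domain_features(np.array(x)) == pytest.approx(expected)


def test_time_domain_sign_symmetry():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    assert time_domain_features(x) == time_domain_features(-x)


def test_time_domain_matches_bruteforce_on_100_vectors():
    rng = np.random.default_rng(1)
    for _ in range(100):
        x = rng.standard_normal(rng.integers(2, 120))
        fast = time_domain_features(x)
        slow = brute_force_tdf(list(x))
        # MAV/WL agree up to float summation order; ZC is an exact count
        assert fast[0] == pytest.approx(slow[0], rel=1e-12)
        assert fast[1] == pytest.approx(slow[1], rel=1e-12)
        assert fast[2] == slow[2]


def test_too_short_vector_errors():
    with pytest.raises(ValueError):
        time_domain_features(np.array([1.0]))


class TestBurgAR:
    def test_recovers_ar2_coefficients(self):
        """The generating recursion x_t = 0.5 x_{t-1} - 0.3 x_{t-2} + e_t is the oracle."""
        rng = np.random.default_rng(0)
        e = rng.standard_normal(10_000)
        x = np.zeros(10_000)
        for t in range(2, 10_000):
            x[t] = 0.5 * x[t - 1] - 0.3 * x[t - 2] + e[t]
        a = ar_features(x, order=6)
        assert a[0] == pytest.approx(0.5, abs=0.05)
        assert a[1] == pytest.approx(-0.3, abs=0.05)
        assert np.all(np.abs(a[2:]) < 0.05)

    def test_white_noise_has_no_ar_structure(self):
        rng = np.random.default_rng(1)
        a = ar_features(rng.standard_normal(10_000), order=6)
        assert np.all(np.abs(a) < 0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        np.testing.assert_allclose(ar_features(x), ar_features(10 * x), rtol=1e-9)

    def test_constant_signal_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            a = ar_features(np.full(100, 2.0))
        assert np.all(a == 0)


class TestWelchPSD:
    def test_parseval_check_on_white_noise(self):
        """Integrated PSD matches the sample variance within 5% (periodogram-sum oracle)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(6000)
        from scipy.signal import welch

        freqs, pxx = welch(x, fs=1500.0, window="hann", nperseg=128, noverlap=64)
        total = np.trapezoid(pxx, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)
        # mean in-band PSD of white noise ~ total power / Nyquist bandwidth
        assert psd_mean(x, 1500.0) == pytest.approx(np.var(x) / 750.0, rel=0.15)

    def test_zero_signal_gives_zero(self):
        assert psd_mean(np.zeros(300), 1500.0) == 0.0

    def test_in_band_tone_outranks_out_of_band_tone(self):
        t = np.arange(3000) / 1500.0
        in_band = np.sin(2 * np.pi * 100 * t)
        out_band = np.sin(2 * np.pi * 600 * t)
        assert psd_mean(in_band, 1500.0) > psd_mean(out_band, 1500.0)

    def test_band_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            psd_mean(np.zeros(300), 500.0)


class TestFeatureMatrix:
    def test_shape_and_names(self, small_windows):
        ws = small_windows.subset(np.arange(28))
        X, y = build_feature_matrix(ws)
        assert X.shape == (28, 12 * 10)
        assert len(y) == 28
        assert len(feature_names(12)) == 120
        assert np.all(np.isfinite(X))

    def test_row_permutation_equivariance(self, small_windows):
        ws = small_windows.subset(np.arange(10))
        X, _ = build_feature_matrix(ws)
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        Xp, _ = build_feature_matrix(ws.subset(perm))
        np.testing.assert_allclose(Xp, X[perm])

    def test_all_zero_windows_give_zero_features(self):
        from synergynet.io import WindowSet

        ws = WindowSet(np.zeros((3, 2, 100)), [0, 0, 0], ["s"] * 3,
                       ["s/t"] * 3, [0, 1, 2], {"rate_hz": 1500.0})
        X, _ = build_feature_matrix(ws)
        assert np.all(X == 0)

    def test_extraction_is_deterministic(self, small_windows):
        ws = small_windows.subset(np.arange(5))
        X1, _ = build_feature_matrix(ws)
        X2, _ = build_feature_matrix(ws)
        np.testing.assert_array_equal(X1, X2)


class TestBaselines:
    def test_stated_hyperparameters(self):
        assert configure_baseline("RBFSVM").params["C"] == 1.9
        assert configure_baseline("RBFSVM").params["multiclass"] == "ovo"
        knn = configure_baseline("KNN").params
        assert knn["n_neighbors"] == 1 and knn["metric"] == "mahalanobis"
        assert configure_baseline("ANN").params["hidden_units"] == 28
        assert configure_baseline("LSVM").params["C"] == 1.0

    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(ValueError) as exc:
            configure_baseline("XGBOOST")
        for name in BASELINE_NAMES:
            assert name in str(exc.value)

    @pytest.mark.parametrize("name", BASELINE_NAMES)
    @pytest.mark.parametrize("mode", ["within", "cross"])
    def test_all_baselines_fit_and_predict(self, name, mode, small_windows):
        ws = small_windows
        X, y = build_feature_matrix(ws)
        cw = compute_class_weights(y)
        clf = make_classifier(configure_baseline(name), cw, mode=mode, seed=0)
        clf.fit(X, y)
        pred = clf.predict(X)
        assert pred.shape == y.shape
        # every baseline at least memorizes an easy training set decently
        assert np.mean(pred == y) > 0.5

    def test_rbfsvm_beats_chance_on_simulator_features(self, small_windows):
        """Class-dependent channel loadings are recoverable from the features."""
        ws = small_windows
        trials = ws.trial_ids.astype(str)
        train_mask = np.array([t.endswith("_00") for t in trials])
        Xtr, ytr = build_feature_matrix(ws.subset(train_mask))
        Xte, yte = build_feature_matrix(ws.subset(~train_mask))
        clf = make_classifier(configure_baseline("RBFSVM"), compute_class_weights(ytr))
        clf.fit(Xtr, ytr)
        acc = np.mean(clf.predict(Xte) == yte)
        assert acc > 0.8  # chance is 0.25
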