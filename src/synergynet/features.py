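"""Handcrafted sEMG features and the classical baseline classifiers.

Per channel and window the feature set is the classical myoelectric quintet:
mean absolute value (MAV), waveform length (WL), zero crossings (ZC), the
six coefficients of a Burg-fitted autoregressive model, and the mean Welch
power spectral density over the 10-450 Hz band — ten numbers per channel,
``C * 10`` per window.

The seven baseline classifiers (LDA, decision tree, kernel-density naive
Bayes, linear and RBF SVM, 1-NN with Mahalanobis metric, and a single
hidden-layer neural net) are configured with the hyperparameters of the
comparison study and honor inverse-frequency class weights where the
underlying estimator supports weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.regression.linear_model import burg

from .io import WindowSet
from .preprocess import ClassWeights

__all__ = [
    "time_domain_features",
    "ar_features",
    "psd_mean",
    "build_feature_matrix",
    "feature_names",
    "ClassifierSpec",
    "configure_baseline",
    "make_classifier",
    "BASELINE_NAMES",
]

AR_ORDER = 6
FEATURES_PER_CHANNEL = 3 + AR_ORDER + 1  # MAV, WL, ZC, AR1..6, PSD


def time_domain_features(x: np.ndarray, zc_deadband: float = 0.0) -> tuple[float, float, int]:
    """Return (MAV, WL, ZC) of a 1-D window.

    MAV is the mean absolute value; WL the summed absolute first difference;
    ZC counts consecutive sample pairs with strictly opposite signs whose
    difference exceeds the dead-band threshold (default 0: pure sign change).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("time-domain features need a 1-D vector of length >= 2")
    mav = float(np.mean(np.abs(x)))
    diffs = np.diff(x)
    wl = float(np.sum(np.abs(diffs)))
    sign_change = (x[:-1] * x[1:]) < 0
    if zc_deadband > 0:
        sign_change &= np.abs(diffs) >= zc_deadband
    zc = int(np.count_nonzero(sign_change))
    return mav, wl, zc


def ar_features(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg-method AR coefficients with convention ``x_t ~= sum_j a_j x_{t-j}``.

    A constant input has no AR structure to estimate; it yields a zero vector
    with a warning (so batch feature extraction tolerates silent channels).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order + 1:
        raise ValueError(f"need more than {order + 1} samples for order-{order} AR fit")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: AR coefficients set to zero", stacklevel=2)
        return np.zeros(order)
    coeffs, _sigma2 = burg(x, order=order, demean=True)
    return np.asarray(coeffs, dtype=float)


def psd_mean(
    x: np.ndarray,
    rate_hz: float,
    band: tuple[float, float] = (10.0, 450.0),
    nperseg: int = 128,
) -> float:
    """Mean of the Welch PSD estimate (Hann window, 50% overlap) over ``band``."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("psd_mean needs at least 64 samples")
    if band[1] >= rate_hz / 2:
        raise ValueError(f"band {band} exceeds Nyquist {rate_hz / 2} Hz")
    nperseg = min(nperseg, x.size)
    freqs, pxx = sp_signal.welch(
        x, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.mean(pxx[in_band]))


def feature_names(n_channels: int) -> list[str]:
    names = []
    for c in range(n_channels):
        names += [f"ch{c:02d}_mav", f"ch{c:02d}_wl", f"ch{c:02d}_zc"]
        names += [f"ch{c:02d}_ar{j}" for j in range(1, AR_ORDER + 1)]
        names += [f"ch{c:02d}_psd"]
    return names


def build_feature_matrix(ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Extract the ``(N_w, C*10)`` feature matrix and labels from a window set.

    Columns are channel-major in the order given by :func:`feature_names`.
    Deterministic: no randomness anywhere in the extractors.
    """
    if len(ws) == 0:
        raise ValueError("empty WindowSet")
    rate = float(ws.meta.get("rate_hz", 1500.0))
    n_w, n_ch, _ = ws.windows.shape
    out = np.zeros((n_w, n_ch * FEATURES_PER_CHANNEL))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # silent channels are legitimate here
        for i in range(n_w):
            col = 0
            for c in range(n_ch):
                x = ws.windows[i, c]
                mav, wl, zc = time_domain_features(x)
                out[i, col : col + 3] = (mav, wl, zc)
                out[i, col + 3 : col + 3 + AR_ORDER] = ar_features(x)
                out[i, col + 3 + AR_ORDER] = psd_mean(x, rate) if mav > 0 else 0.0
                col += FEATURES_PER_CHANNEL
    return out, ws.labels.copy()


# --------------------------------------------------------------------------
# Baseline classifiers
# --------------------------------------------------------------------------

BASELINE_NAMES = ("LDA", "DT", "BES", "LSVM", "RBFSVM", "KNN", "ANN")


@dataclass
class ClassifierSpec:
    """A named baseline with its study hyperparameters."""

    name: str
    params: dict = field(default_factory=dict)
    notes: str = ""


def configure_baseline(name: str) -> ClassifierSpec:
    """Return the stated hyperparameter configuration for a baseline name."""
    key = name.upper()
    specs = {
        "LDA": ClassifierSpec("LDA", {"covariance": "per-mode"},
                              "full covariance within-subject, diagonal cross-subject"),
        "DT": ClassifierSpec("DT", {"max_splits": 100},
                             "realized as max_leaf_nodes = 101 (splits = leaves - 1)"),
        "BES": ClassifierSpec("BES", {"kernel": "gaussian-kde"},
                              "kernel-density class-conditional naive Bayes"),
        "LSVM": ClassifierSpec("LSVM", {"kernel": "linear", "C": 1.0, "multiclass": "ovo"}),
        "RBFSVM": ClassifierSpec("RBFSVM", {"kernel": "rbf", "C": 1.9, "multiclass": "ovo"}),
        "KNN": ClassifierSpec("KNN", {"n_neighbors": 1, "metric": "mahalanobis"}),
        "ANN": ClassifierSpec("ANN", {"hidden_units": 28}),
    }
    if key not in specs:
        raise ValueError(f"unknown baseline {name!r}; valid: {', '.join(BASELINE_NAMES)}")
    return specs[key]


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """LDA with a shared *diagonal* covariance (the cross-subject variant)."""

    def fit(self, X, y):
        X, y = np.asarray(X, float), np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        self.var_ = resid.var(axis=0) + 1e-9
        self.log_priors_ = np.log(
            np.array([np.mean(y == c) for c in self.classes_])
        )
        return self

    def _scores(self, X):
        X = np.asarray(X, float)
        # log-likelihood under N(mean_c, diag(var)) + log prior, constants dropped
        return np.stack(
            [
                -0.5 * np.sum((X - m) ** 2 / self.var_, axis=1) + p
                for m, p in zip(self.means_, self.log_priors_)
            ],
            axis=1,
        )

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


class KernelDensityNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a 1-D Gaussian KDE per feature per class."""

    def fit(self, X, y):
        X, y = np.asarray(X, float), np.asarray(y)
        self.classes_ = np.unique(y)
        self.log_priors_ = np.log(np.array([np.mean(y == c) for c in self.classes_]))
        self.kdes_ = []
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) == 0:  # degenerate feature: spike at the constant
                    feats.append(("const", float(col[0])))
                else:
                    feats.append(("kde", gaussian_kde(col)))
                # NB independence assumption: one marginal density per feature
            self.kdes_.append(feats)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        scores = np.tile(self.log_priors_, (len(X), 1))
        for ci, feats in enumerate(self.kdes_):
            for j, (kind, dens) in enumerate(feats):
                if kind == "const":
                    scores[:, ci] += np.where(np.isclose(X[:, j], dens), 0.0, -50.0)
                else:
                    scores[:, ci] += np.log(dens(X[:, j]) + 1e-300)
        return self.classes_[np.argmax(scores, axis=1)]


class MahalanobisKNN(BaseEstimator, ClassifierMixin):
    """1-NN with Mahalanobis metric; the inverse covariance comes from the fit data."""

    def __init__(self, n_neighbors: int = 1):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, float)
        cov = np.cov(X, rowvar=False) + 1e-6 * np.eye(X.shape[1])
        self.knn_ = KNeighborsClassifier(
            n_neighbors=self.n_neighbors,
            metric="mahalanobis",
            metric_params={"VI": np.linalg.pinv(cov)},
            algorithm="brute",
        )
        self.knn_.fit(X, y)
        self.classes_ = self.knn_.classes_
        return self

    def predict(self, X):
        return self.knn_.predict(np.asarray(X, float))


def make_classifier(
    spec: ClassifierSpec,
    class_weights: ClassWeights | None = None,
    mode: str = "within",
    seed: int = 0,
):
    """Build the sklearn estimator for a baseline spec.

    Features are standardized inside the pipeline (the raw features span
    several orders of magnitude, which would otherwise dominate the kernel
    machines).  Class weights are passed to estimators that support them
    (SVMs, tree, LDA priors); the KNN and ANN baselines have no weighting
    hook, which is documented behavior.
    """
    cw = class_weights.weights if class_weights else None
    name = spec.name
    if name == "LDA":
        if mode == "cross":
            est = DiagonalLDA()
        else:
            priors = None
            if cw:
                p = np.array([cw[k] for k in sorted(cw)])
                priors = p / p.sum()
            est = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    elif name == "DT":
        est = DecisionTreeClassifier(max_leaf_nodes=101, class_weight=cw, random_state=seed)
    elif name == "BES":
        est = KernelDensityNB()
    elif name == "LSVM":
        est = SVC(kernel="linear", C=1.0, class_weight=cw, decision_function_shape="ovo")
    elif name == "RBFSVM":
        est = SVC(kernel="rbf", C=1.9, class_weight=cw, decision_function_shape="ovo")
    elif name == "KNN":
        est = MahalanobisKNN(n_neighbors=1)
    elif name == "ANN":
        est = MLPClassifier(hidden_layer_sizes=(28,), max_iter=500, random_state=seed)
    else:
        raise ValueError(f"unknown baseline {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])
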