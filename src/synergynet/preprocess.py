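"""Filtering, preparation-period extraction, windowing, class weights.

The preprocessing chain mirrors standard sEMG practice: a mains notch filter
(50 Hz) plus a 10-450 Hz bandpass keep the physiologically informative band,
the 2 s movement-preparation interval is cropped out of each trial, and the
cropped signal is cut into 200 ms (300-sample at 1500 Hz) sliding windows
with a 100-sample step.  Filters run once per trial, before segmentation,
and are applied forward-backward (zero phase) so window boundaries carry no
filter latency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .io import Recording, WindowSet

__all__ = [
    "FilterSpec",
    "ClassWeights",
    "apply_filters",
    "extract_preparation",
    "segment_windows",
    "compute_class_weights",
    "build_windows",
]


@dataclass(frozen=True)
class FilterSpec:
    """Notch + bandpass settings.

    Defaults: 50 Hz notch (Q = 30) and a 4th-order Butterworth bandpass with
    10-450 Hz edges, both applied zero-phase (``filtfilt``).
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    bandpass_hz: tuple[float, float] = (10.0, 450.0)
    bandpass_order: int = 4

    def validate(self, rate_hz: float) -> None:
        nyq = rate_hz / 2.0
        low, high = self.bandpass_hz
        if not (0 < low < high < nyq):
            raise ValueError(
                f"bandpass edges {self.bandpass_hz} must satisfy 0 < low < high < {nyq} Hz"
            )
        if not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch {self.notch_hz} Hz outside (0, {nyq}) Hz")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights: count(majority) / count(class).

    The most frequent class gets weight exactly 1; rarer classes get
    proportionally larger weights, compensating the walking-heavy trial
    design (20 walking trials vs 10 for the other movements).
    """

    weights: dict[int, float]

    def as_array(self, n_classes: int) -> np.ndarray:
        return np.array([self.weights.get(c, 1.0) for c in range(n_classes)])


def apply_filters(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Return ``rec`` with the notch and bandpass applied channel-wise, zero-phase."""
    spec = spec or FilterSpec()
    spec.validate(rec.rate_hz)
    b_n, a_n = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.rate_hz)
    sos = signal.butter(
        spec.bandpass_order, spec.bandpass_hz, btype="bandpass", fs=rec.rate_hz, output="sos"
    )
    x = signal.filtfilt(b_n, a_n, rec.samples, axis=1)
    x = signal.sosfiltfilt(sos, x, axis=1)
    return dataclasses.replace(rec, samples=x)


def extract_preparation(rec: Recording) -> Recording:
    """Crop a recording to its annotated movement-preparation interval."""
    if "preparation" not in rec.annotations:
        raise ValueError(
            "recording has no 'preparation' annotation; supply the interval explicitly"
        )
    start, end = rec.annotations["preparation"]
    if end <= start:
        raise ValueError(f"empty preparation interval [{start}, {end})")
    cropped = rec.crop(start, end)
    return cropped


def n_segments(T: int, window_len: int, step: int) -> int:
    """Number of full windows of ``window_len`` at stride ``step`` in ``T`` samples."""
    if T < window_len:
        raise ValueError(f"signal length {T} shorter than window {window_len}")
    return (T - window_len) // step + 1


def segment_windows(rec: Recording, window_len: int = 300, step: int = 100) -> WindowSet:
    """Cut a recording into overlapping windows ``(N_w, C, window_len)``.

    Trailing samples shorter than one window are discarded.  Windows are
    emitted in temporal order; ``window_order`` is their index in the trial.
    """
    if window_len < 1 or step < 1:
        raise ValueError("window_len and step must be positive")
    n_w = n_segments(rec.n_samples, window_len, step)
    starts = np.arange(n_w) * step
    windows = np.stack([rec.samples[:, s : s + window_len] for s in starts])
    return WindowSet(
        windows=windows,
        labels=np.full(n_w, int(rec.label)),
        subject_ids=np.full(n_w, rec.subject_id, dtype=object),
        trial_ids=np.full(n_w, f"{rec.subject_id}/{rec.trial_id}", dtype=object),
        window_order=np.arange(n_w),
        meta={"window_len": window_len, "step": step, "rate_hz": rec.rate_hz},
    )


def compute_class_weights(labels: Sequence[int] | np.ndarray) -> ClassWeights:
    """Inverse-frequency class weights, majority class pinned to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot compute class weights from empty labels")
    classes, counts = np.unique(labels, return_counts=True)
    majority = counts.max()
    return ClassWeights({int(c): majority / n for c, n in zip(classes, counts)})


def build_windows(
    recordings: Iterable[Recording],
    spec: FilterSpec | None = None,
    window_len: int = 300,
    step: int = 100,
) -> WindowSet:
    """Full per-trial chain: filter -> crop preparation -> segment -> concatenate.

    Filtering happens on the whole trial before cropping so filter edge
    transients fall outside the analysed interval whenever the annotation
    leaves margin, and exactly once per trial (the window set records the
    filter fingerprint in ``meta``).
    """
    spec = spec or FilterSpec()
    parts = []
    for rec in recordings:
        filtered = apply_filters(rec, spec)
        prep = extract_preparation(filtered)
        parts.append(segment_windows(prep, window_len=window_len, step=step))
    ws = WindowSet.concatenate(parts)
    ws.meta["filters"] = dataclasses.asdict(spec)
    return ws
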