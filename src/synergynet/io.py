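"""Data model and file I/O for sEMG recordings, manifests, and window sets.

A :class:`Recording` is one trial of multichannel surface EMG: a ``C x T``
matrix of microvolt-scale samples at a fixed sampling rate, tagged with the
subject, the trial, and the lower-limb movement the subject was preparing.
On disk a recording is a plain CSV matrix (rows = samples, one column per
channel) plus a JSON sidecar carrying the rate, channel names, label and
annotations, so every artifact is self-describing and diffable.

Channel convention: channels ``0 .. C/2-1`` are left-side muscles and
``C/2 .. C-1`` their mirrored right-side counterparts, so the symmetric
partner of channel ``k`` is ``k + C/2``.  Time is sample-indexed, 0-based,
with half-open annotation intervals ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MovementLabel",
    "Recording",
    "WindowSet",
    "ManifestEntry",
    "DatasetManifest",
    "read_recording",
    "write_recording",
    "load_dataset",
]


class MovementLabel(enum.IntEnum):
    """The four lower-limb movement classes, coded 0..3."""

    SIT = 0
    STAND = 1
    WALK = 2
    UPSTAIRS = 3

    @classmethod
    def from_any(cls, value) -> "MovementLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls[value.upper()]
        return cls(int(value))


N_CLASSES = len(MovementLabel)


@dataclass
class Recording:
    """One subject/trial multichannel sEMG time series.

    Parameters
    ----------
    samples
        Real matrix of shape ``(C, T)``, arbitrary (microvolt-scale) units.
    rate_hz
        Sampling rate in Hz (positive).
    channel_names
        ``C`` channel names; auto-generated ``ch00..`` when omitted.
    annotations
        Named half-open sample intervals, e.g. ``{"preparation": (0, 3000)}``.
    """

    samples: np.ndarray
    rate_hz: float = 1500.0
    channel_names: list[str] | None = None
    subject_id: str = "S0"
    trial_id: str = "T0"
    label: MovementLabel = MovementLabel.SIT
    annotations: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (C x T) matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.label = MovementLabel.from_any(self.label)
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")
        for name, (start, end) in self.annotations.items():
            if not (0 <= start < end <= self.n_samples):
                raise ValueError(
                    f"annotation {name!r}=[{start}, {end}) outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def crop(self, start: int, end: int) -> "Recording":
        """Return a copy restricted to samples ``[start, end)``."""
        if not (0 <= start < end <= self.n_samples):
            raise ValueError(f"crop [{start}, {end}) outside [0, {self.n_samples})")
        return dataclasses.replace(
            self,
            samples=self.samples[:, start:end].copy(),
            annotations={},
        )


@dataclass
class WindowSet:
    """Segmented analysis windows: tensor ``(N_w, C, L)`` with labels.

    ``window_order`` gives each window's temporal index within its source
    trial (strictly increasing per trial); ``trial_ids`` records provenance so
    splits and batch construction can operate at the trial level.
    """

    windows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    window_order: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=object)
        self.window_order = np.asarray(self.window_order, dtype=int)
        n = len(self.windows)
        for name in ("labels", "subject_ids", "trial_ids", "window_order"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n} windows")
        if self.windows.ndim != 3:
            raise ValueError("windows must have shape (N_w, C, L)")
        # window_order is each window's temporal index within its trial;
        # segmentation emits it strictly increasing, but reordered views
        # (subsets, permutations) are legitimate — consumers that need the
        # temporal order sort on it explicitly.

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return WindowSet(
            self.windows[idx],
            self.labels[idx],
            self.subject_ids[idx],
            self.trial_ids[idx],
            self.window_order[idx],
            dict(self.meta),
        )

    @staticmethod
    def concatenate(parts: Sequence["WindowSet"]) -> "WindowSet":
        parts = list(parts)
        if not parts:
            raise ValueError("cannot concatenate zero WindowSets")
        return WindowSet(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.trial_ids for p in parts]),
            np.concatenate([p.window_order for p in parts]),
            dict(parts[0].meta),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            windows=self.windows,
            labels=self.labels,
            subject_ids=self.subject_ids.astype(str),
            trial_ids=self.trial_ids.astype(str),
            window_order=self.window_order,
            meta=json.dumps(self.meta),
        )

    @staticmethod
    def load(path: str | Path) -> "WindowSet":
        data = np.load(path, allow_pickle=False)
        return WindowSet(
            data["windows"],
            data["labels"],
            data["subject_ids"].astype(object),
            data["trial_ids"].astype(object),
            data["window_order"],
            json.loads(str(data["meta"])),
        )


# --------------------------------------------------------------------------
# Recording file I/O: CSV matrix + JSON sidecar
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as a CSV matrix (rows = samples) plus a JSON sidecar.

    Values are printed with 17 significant digits so a read/write round trip
    reproduces the float64 samples bit-exactly.
    """
    path = Path(path)
    np.savetxt(path, rec.samples.T, delimiter=",", fmt="%.17g")
    sidecar = {
        "rate_hz": rec.rate_hz,
        "channel_names": rec.channel_names,
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "label": rec.label.name,
        "annotations": {k: list(v) for k, v in rec.annotations.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


class RecordingParseError(ValueError):
    """Raised when a recording CSV contains non-numeric or non-finite cells."""


def read_recording(path: str | Path, meta: Mapping | None = None) -> Recording:
    """Read a CSV numeric matrix (+ JSON sidecar) into a :class:`Recording`.

    ``meta`` overrides/supplies sidecar fields (``rate_hz`` is required from
    one of the two sources).  Non-numeric or NaN cells raise
    :class:`RecordingParseError` naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    frame = pd.read_csv(path, header=None, float_precision="round_trip")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise RecordingParseError(
            f"{path}: non-numeric or non-finite value at row {r}, column {c}: "
            f"{frame.iat[r, c]!r}"
        )
    sidecar_file = _sidecar_path(path)
    sidecar: dict = {}
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
    if meta:
        sidecar.update(meta)
    if "rate_hz" not in sidecar:
        raise ValueError(f"{path}: sampling rate missing from sidecar and meta")
    annotations = {k: tuple(v) for k, v in sidecar.get("annotations", {}).items()}
    return Recording(
        samples=numeric.to_numpy(dtype=float).T,
        rate_hz=float(sidecar["rate_hz"]),
        channel_names=sidecar.get("channel_names"),
        subject_id=str(sidecar.get("subject_id", "S0")),
        trial_id=str(sidecar.get("trial_id", path.stem)),
        label=MovementLabel.from_any(sidecar.get("label", 0)),
        annotations=annotations,
    )


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------


@dataclass
class ManifestEntry:
    trial_id: str
    label: MovementLabel
    path: str | None = None
    annotations: dict[str, tuple[int, int]] = field(default_factory=dict)
    recording: Recording | None = None  # in-memory datasets skip the disk trip


@dataclass
class DatasetManifest:
    """Maps subject_id -> trial entries; serializable as a single JSON file."""

    entries: dict[str, list[ManifestEntry]] = field(default_factory=dict)
    root: str | None = None

    def subjects(self) -> list[str]:
        return sorted(self.entries)

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def save(self, path: str | Path) -> None:
        payload = {
            "root": self.root,
            "entries": {
                subj: [
                    {
                        "trial_id": e.trial_id,
                        "label": e.label.name,
                        "path": e.path,
                        "annotations": {k: list(v) for k, v in e.annotations.items()},
                    }
                    for e in trials
                ]
                for subj, trials in self.entries.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load(path: str | Path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        entries = {
            subj: [
                ManifestEntry(
                    trial_id=e["trial_id"],
                    label=MovementLabel.from_any(e["label"]),
                    path=e.get("path"),
                    annotations={k: tuple(v) for k, v in e.get("annotations", {}).items()},
                )
                for e in trials
            ]
            for subj, trials in payload["entries"].items()
        }
        return DatasetManifest(entries=entries, root=payload.get("root"))


def load_dataset(manifest: DatasetManifest) -> dict[str, list[Recording]]:
    """Load all recordings, grouped by subject, in (subject, trial) order.

    Ordering is deterministic regardless of manifest entry order; duplicate
    trial ids within a subject or unresolvable paths are errors.
    """
    if manifest.n_trials == 0:
        logger.warning("empty manifest: no recordings to load")
        return {}
    root = Path(manifest.root) if manifest.root else None
    out: dict[str, list[Recording]] = {}
    for subject in manifest.subjects():
        trials = sorted(manifest.entries[subject], key=lambda e: e.trial_id)
        seen: set[str] = set()
        recs: list[Recording] = []
        for entry in trials:
            if entry.trial_id in seen:
                raise ValueError(f"duplicate trial_id {entry.trial_id!r} for subject {subject!r}")
            seen.add(entry.trial_id)
            if entry.recording is not None:
                recs.append(entry.recording)
                continue
            if entry.path is None:
                raise ValueError(f"manifest entry {subject}/{entry.trial_id} has no path or recording")
            path = Path(entry.path)
            if root is not None and not path.is_absolute():
                path = root / path
            if not path.exists():
                raise FileNotFoundError(f"manifest references missing file: {path}")
            rec = read_recording(path)
            rec.subject_id = subject
            rec.trial_id = entry.trial_id
            rec.label = entry.label
            if entry.annotations:
                rec.annotations.update(entry.annotations)
            recs.append(rec)
        out[subject] = recs
        logger.info("subject %s: %d trials loaded", subject, len(recs))
    return out
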