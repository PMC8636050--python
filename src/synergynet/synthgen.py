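"""Synthetic sEMG cohorts with planted muscle-synergy ground truth.

The simulator emulates the study's acquisition setting — 12 channels at
1500 Hz, 2 s movement-preparation segments, four movement classes, trial
counts of 10/10/20/10 (sit/stand/walk/upstairs) per subject — with a signal
model standard for surrogate surface EMG: amplitude-modulated band-limited
(20-450 Hz) Gaussian noise.

Channel ``c`` of a trial of class ``m`` is::

    loading[c, m] * gain[c] * envelope(t) * carrier_c(t)  +  mains  +  floor

where ``carrier_c`` shares a common band-limited component with the
symmetric partner channel ``c +- C/2`` (weight ``symmetric_corr``), the
envelope ramps up/down over 0.2 s at the window edges, ``mains`` is a 50 Hz
sinusoid, and ``floor`` is white noise.  Per-subject multiplicative
perturbation of the loadings emulates muscle compensation — the reason
cross-subject prediction is harder than within-subject.

The planted per-class loading matrix is the ground truth that the synergy
analysis is tested against: a planted channel is one whose loading exceeds
half the class maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io import DatasetManifest, ManifestEntry, MovementLabel, Recording, write_recording

__all__ = [
    "SynergyGroundTruth",
    "SubjectProfile",
    "SimConfig",
    "default_ground_truth",
    "generate_subject",
    "generate_cohort",
    "planted_channels",
]

#: trials per class per subject in the study design (walking is doubled)
DEFAULT_TRIALS = {
    MovementLabel.SIT: 10,
    MovementLabel.STAND: 10,
    MovementLabel.WALK: 20,
    MovementLabel.UPSTAIRS: 10,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (defaults mirror the acquisition)."""

    n_channels: int = 12
    rate_hz: float = 1500.0
    prep_seconds: float = 2.0
    n_classes: int = 4
    n_subjects: int = 5
    trials_per_class: dict | None = None  # MovementLabel -> count; None = study design
    carrier_band: tuple[float, float] = (20.0, 450.0)
    mains_hz: float = 50.0
    mains_amplitude: float = 0.2
    noise_floor: float = 0.05
    loading_perturbation: float = 0.15
    gain_spread: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        low, high = self.carrier_band
        if not (0 < low < high < self.rate_hz / 2):
            raise ValueError(f"carrier band {self.carrier_band} outside (0, Nyquist)")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for count in self.trial_counts().values():
            if count < 1:
                raise ValueError("trials per class must be >= 1")

    def trial_counts(self) -> dict[MovementLabel, int]:
        if self.trials_per_class is None:
            return dict(DEFAULT_TRIALS)
        return {MovementLabel.from_any(k): int(v) for k, v in self.trials_per_class.items()}

    @property
    def n_samples(self) -> int:
        return int(round(self.prep_seconds * self.rate_hz))


@dataclass
class SynergyGroundTruth:
    """Planted per-class channel loadings and the activation envelope."""

    loadings: np.ndarray  # (C, n_classes), non-negative
    envelope_ramp_s: float = 0.2
    symmetric_corr: float = 0.4

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if np.any(self.loadings < 0):
            raise ValueError("synergy loadings must be non-negative")
        if not (0.0 <= self.symmetric_corr <= 1.0):
            raise ValueError("symmetric_corr must lie in [0, 1]")
        sets = [frozenset(self.planted(m)) for m in range(self.loadings.shape[1])]
        if any(not s for s in sets):
            raise ValueError("every class needs at least one planted channel")
        if len(set(sets)) < 2 and len(sets) > 1:
            raise ValueError("planted channel sets must differ between at least two classes")

    def planted(self, movement: int | MovementLabel) -> list[int]:
        """Channels whose loading exceeds half the class maximum (the oracle set)."""
        col = self.loadings[:, int(movement)]
        return sorted(np.flatnonzero(col > 0.5 * col.max()).tolist())


def planted_channels(gt: SynergyGroundTruth, movement: int | MovementLabel) -> list[int]:
    """Oracle channel set for a movement class (see :meth:`SynergyGroundTruth.planted`)."""
    return gt.planted(movement)


def default_ground_truth(n_channels: int = 12, n_classes: int = 4,
                         base_loading: float = 0.15) -> SynergyGroundTruth:
    """The default planted synergy structure.

    Each class activates two symmetric muscle pairs (four channels) at full
    loading over a low background; class sets are distinct but overlap, as
    real movement synergies do.
    """
    if n_channels % 2 != 0:
        raise ValueError("default ground truth assumes symmetric channel pairs")
    half = n_channels // 2
    loadings = np.full((n_channels, n_classes), base_loading)
    for m in range(n_classes):
        left = [m % half, (m + 1 + m // half) % half]
        for c in left:
            loadings[c, m] = 1.0
            loadings[c + half, m] = 1.0  # symmetric partner
    return SynergyGroundTruth(loadings=loadings)


@dataclass
class SubjectProfile:
    """Per-subject deviation from the cohort ground truth (muscle compensation)."""

    subject_id: str
    loading_scale: np.ndarray  # (C,), multiplicative, >= 0
    gain: np.ndarray  # (C,)
    seed: int

    def __post_init__(self) -> None:
        self.loading_scale = np.asarray(self.loading_scale, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.loading_scale < 0):
            raise ValueError("perturbed loadings must remain non-negative")


def _subject_profile(sim: SimConfig, subject_index: int) -> SubjectProfile:
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 1, subject_index]))
    # lognormal multiplicative perturbation keeps loadings non-negative
    scale = np.exp(rng.normal(0.0, sim.loading_perturbation, size=sim.n_channels))
    gain = np.exp(rng.normal(0.0, sim.gain_spread, size=sim.n_channels))
    return SubjectProfile(
        subject_id=f"S{subject_index:02d}", loading_scale=scale, gain=gain,
        seed=subject_index,
    )


def _bandlimit(white: np.ndarray, sim: SimConfig) -> np.ndarray:
    sos = signal.butter(4, sim.carrier_band, btype="bandpass", fs=sim.rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    # renormalize so the carrier has unit RMS regardless of band width
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-12)


def _envelope(sim: SimConfig, ramp_s: float) -> np.ndarray:
    T = sim.n_samples
    n_ramp = int(round(ramp_s * sim.rate_hz))
    env = np.ones(T)
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _make_trial(
    gt: SynergyGroundTruth,
    prof: SubjectProfile,
    sim: SimConfig,
    movement: MovementLabel,
    trial_index: int,
) -> Recording:
    C, T = sim.n_channels, sim.n_samples
    rng = np.random.default_rng(
        np.random.SeedSequence([sim.seed, 2, prof.seed, int(movement), trial_index])
    )
    half = C // 2
    own = _bandlimit(rng.standard_normal((C, T)), sim)
    shared_half = _bandlimit(rng.standard_normal((half, T)), sim)
    shared = np.concatenate([shared_half, shared_half])  # identical for pair (k, k+C/2)
    sc = gt.symmetric_corr
    carrier = np.sqrt(1.0 - sc**2) * own + sc * shared
    env = _envelope(sim, gt.envelope_ramp_s)
    amp = gt.loadings[:, int(movement)] * prof.loading_scale * prof.gain
    x = amp[:, None] * env[None, :] * carrier
    t = np.arange(T) / sim.rate_hz
    phase = rng.uniform(0, 2 * np.pi)
    x += sim.mains_amplitude * np.sin(2 * np.pi * sim.mains_hz * t + phase)[None, :]
    x += sim.noise_floor * rng.standard_normal((C, T))
    return Recording(
        samples=x,
        rate_hz=sim.rate_hz,
        subject_id=prof.subject_id,
        trial_id=f"{movement.name.lower()}_{trial_index:02d}",
        label=movement,
        annotations={"preparation": (0, T)},
    )


def generate_subject(
    gt: SynergyGroundTruth, prof: SubjectProfile, sim: SimConfig
) -> list[Recording]:
    """All trials for one subject, deterministic given (sim.seed, subject, trial)."""
    sim.validate()
    recs = []
    for movement, count in sim.trial_counts().items():
        for k in range(count):
            recs.append(_make_trial(gt, prof, sim, movement, k))
    return recs


def generate_cohort(
    sim: SimConfig,
    gt: SynergyGroundTruth | None = None,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, SynergyGroundTruth]:
    """Generate the full cohort; optionally write CSV+JSON files to ``out_dir``.

    With ``out_dir=None`` the recordings stay in memory (the manifest entries
    carry them directly), which is how the test suite uses the simulator.
    Returns the manifest and the planted ground truth for oracle-based tests.
    """
    sim.validate()
    gt = gt or default_ground_truth(sim.n_channels, sim.n_classes)
    entries: dict[str, list[ManifestEntry]] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for s in range(sim.n_subjects):
        prof = _subject_profile(sim, s)
        recs = generate_subject(gt, prof, sim)
        subject_entries = []
        for rec in recs:
            entry = ManifestEntry(
                trial_id=rec.trial_id, label=rec.label,
                annotations=dict(rec.annotations),
            )
            if out is None:
                entry.recording = rec
            else:
                subj_dir = out / prof.subject_id
                subj_dir.mkdir(exist_ok=True)
                path = subj_dir / f"{rec.trial_id}.csv"
                write_recording(rec, path)
                entry.path = str(path.relative_to(out))
            subject_entries.append(entry)
        entries[prof.subject_id] = subject_entries
    manifest = DatasetManifest(entries=entries, root=str(out) if out else None)
    if out is not None:
        manifest.save(out / "manifest.json")
        np.savetxt(out / "ground_truth_loadings.csv", gt.loadings, delimiter=",")
    return manifest, gt
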