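"""Synthetic mouse-like EEG/EMG recordings with known ground-truth stages.

Stage phenotypes follow the standard rodent scoring conventions: wake is
mixed-frequency low-amplitude EEG with high EMG tone, NREM is
delta-dominant (0.5-4 Hz) high-amplitude EEG with low EMG, and REM is
theta-dominant (5-9 Hz) low-amplitude EEG with near-absent EMG tone.
Stage bouts follow a first-order Markov chain whose stationary mix has
wake predominating; artifact epochs (large transient spikes) are
injected at a configurable rate. Everything is reproducible bit-exactly
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .io import (
    EpochRecord,
    RawRecording,
    StageLabel,
    SAMPLES_PER_RAW_EPOCH,
    STAGES,
    write_stage_labels,
    write_voltage_table,
)

RAW_RATE_HZ = 256


@dataclass(frozen=True)
class BandSpec:
    lo_hz: float
    hi_hz: float
    eeg_amplitude: float
    emg_rms: float


@dataclass(frozen=True)
class StageSignalParams:
    """Per-stage EEG band/amplitude and EMG tone defaults.

    The EMG-tone ordering wake > NREM > REM is what makes the task
    solvable from the EMG channel alone for wake-vs-sleep; the EEG
    delta/theta contrast separates NREM from REM.
    """

    wake: BandSpec = BandSpec(2.0, 20.0, 1.0, 2.0)
    nrem: BandSpec = BandSpec(0.5, 4.0, 3.0, 0.4)
    rem: BandSpec = BandSpec(5.0, 9.0, 1.0, 0.05)
    drift_amplitude: float = 0.5     # slow (<0.2 Hz) baseline wander
    emg_drift_fraction: float = 0.2  # EMG wanders less than EEG, keeping the
                                     # stage-discriminative EMG tone dominant
    mains_hz: float | None = None    # 50/60 Hz contamination, off by default
    mains_amplitude: float = 0.0
    artifact_amplitude: float = 20.0

    def __post_init__(self):
        if not (self.wake.emg_rms > self.nrem.emg_rms > self.rem.emg_rms):
            raise ValueError("EMG tone must satisfy wake > NREM > REM")
        for b in (self.wake, self.nrem, self.rem):
            if not 0 < b.lo_hz < b.hi_hz < 32:
                raise ValueError("EEG bands must lie within (0, 32) Hz")

    def band(self, code: str) -> BandSpec:
        return {"W": self.wake, "N": self.nrem, "R": self.rem}[code]


def _default_transitions() -> np.ndarray:
    # stay-probability 0.9 + jump to the stationary mix: stationary
    # distribution is exactly the target mix by construction
    pi = np.array([0.50, 0.42, 0.08])
    return 0.9 * np.eye(3) + 0.1 * pi[None, :]


@dataclass
class TransitionModel:
    """First-order Markov bout model over (W, N, R) with artifact injection."""

    matrix: np.ndarray = field(default_factory=_default_transitions)
    artifact_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3) or np.any(self.matrix < 0):
            raise ValueError("transition matrix must be 3x3 nonnegative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")

    @property
    def stationary(self) -> np.ndarray:
        """Left eigenvector of the transition matrix with eigenvalue 1."""
        w, v = np.linalg.eig(self.matrix.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        return pi / pi.sum()


def sample_stage_sequence(n_epochs: int, model: TransitionModel) -> list[StageLabel]:
    """Markov-sample a stage sequence, overwriting epochs with A at artifact_rate."""
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    rng = np.random.default_rng(model.seed)
    pi = model.stationary
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(3, p=pi)
    for i in range(1, n_epochs):
        states[i] = rng.choice(3, p=model.matrix[states[i - 1]])
    codes = [STAGES[s] for s in states]
    if model.artifact_rate > 0:
        art = rng.random(n_epochs) < model.artifact_rate
        codes = ["A" if a else c for c, a in zip(codes, art)]
    return [StageLabel(c) for c in codes]


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited noise via a Butterworth band-pass of white noise."""
    white = rng.standard_normal(n + 512)  # padding absorbs filter transients
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=RAW_RATE_HZ, output="sos")
    x = _sig.sosfiltfilt(sos, white)[256:256 + n]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize_epoch(stage: StageLabel, params: StageSignalParams = StageSignalParams(),
                     seed: int = 0, index: int = 0,
                     source_id: str = "synthetic") -> EpochRecord:
    """Generate one 1024-sample (4 s at 256 Hz) epoch of the given stage.

    EEG is band-limited noise plus a sinusoid at a random frequency inside
    the stage band; EMG is broadband noise at the stage's RMS tone.
    Artifact epochs get large-amplitude transient spikes on both channels.
    """
    rng = np.random.default_rng(seed)
    n = SAMPLES_PER_RAW_EPOCH
    t = np.arange(n) / RAW_RATE_HZ

    if stage.is_artifact:
        eeg = rng.standard_normal(n)
        emg = rng.standard_normal(n)
        for ch in (eeg, emg):
            pos = rng.integers(0, n, size=3)
            ch[pos] += rng.choice([-1, 1], size=3) * params.artifact_amplitude
    else:
        band = params.band(stage.code)
        f0 = rng.uniform(band.lo_hz, band.hi_hz)
        phase = rng.uniform(0, 2 * np.pi)
        eeg = band.eeg_amplitude * (
            0.7 * _band_noise(rng, n, band.lo_hz, band.hi_hz)
            + 0.7 * np.sin(2 * np.pi * f0 * t + phase)
        )
        emg = band.emg_rms * rng.standard_normal(n)

    if params.drift_amplitude > 0:
        f_drift = rng.uniform(0.02, 0.2)
        drift = params.drift_amplitude * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        offset = rng.normal(0, params.drift_amplitude)
        eeg = eeg + drift + offset
        emg = emg + params.emg_drift_fraction * (drift + offset)
    if params.mains_hz is not None and params.mains_amplitude > 0:
        mains = params.mains_amplitude * np.sin(2 * np.pi * params.mains_hz * t)
        eeg = eeg + mains
        emg = emg + mains

    return EpochRecord(eeg=eeg, emg=emg, label=stage, index=index, source_id=source_id)


def synthesize_epochs(labels, params: StageSignalParams = StageSignalParams(),
                      seed: int = 0, source_id: str = "synthetic") -> list[EpochRecord]:
    """Generate one epoch per label with per-epoch child seeds from ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(len(labels))
    return [
        synthesize_epoch(lab, params, seed=int(s), index=i, source_id=source_id)
        for i, (lab, s) in enumerate(zip(labels, children))
    ]


def synthesize_recording(n_epochs: int, model: TransitionModel | None = None,
                         params: StageSignalParams = StageSignalParams(),
                         out_dir=None, source_id: str = "synthetic"):
    """Generate a full recording; optionally write voltage/label/manifest files.

    Returns ``(recording, labels)`` and, if ``out_dir`` is given, writes
    ``<source_id>_voltages.csv``, ``<source_id>_stages.txt`` and a manifest
    recording the seed and parameters, in the formats the readers accept.
    """
    model = model or TransitionModel()
    labels = sample_stage_sequence(n_epochs, model)
    epochs = synthesize_epochs(labels, params, seed=model.seed, source_id=source_id)
    eeg = np.concatenate([ep.eeg for ep in epochs])
    emg = np.concatenate([ep.emg for ep in epochs])
    rec = RawRecording(eeg=eeg, emg=emg, sample_rate_hz=RAW_RATE_HZ, source_id=source_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vpath = out_dir / f"{source_id}_voltages.csv"
        lpath = out_dir / f"{source_id}_stages.txt"
        write_voltage_table(vpath, rec)
        write_stage_labels(lpath, labels)
        manifest = out_dir / f"{source_id}_manifest.txt"
        manifest.write_text(
            f"seed = {model.seed}\n"
            f"n_epochs = {n_epochs}\n"
            f"artifact_rate = {model.artifact_rate}\n"
            f"sample_rate_hz = {RAW_RATE_HZ}\n"
            f"stationary_mix = {np.round(model.stationary, 4).tolist()}\n"
        )
        return rec, labels, vpath, lpath
    return rec, labels
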