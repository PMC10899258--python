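"""Per-epoch preprocessing: downsample, filter EMG, baseline-correct, stack.

The chain mirrors what the classifier consumes: each 1024-sample channel
is downsampled fourfold to 256 samples (64 Hz) with a polyphase
anti-aliasing resampler, the EMG (only) is high-passed at 0.5 Hz with a
zero-phase Butterworth filter to strip slow drift, both channels are
baseline-corrected by subtracting the per-epoch mean, artifact-labelled
epochs are discarded, and the survivors are stacked into the model input
tensor of shape (N, 256, 2) with one-hot (N, 3) labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .io import EpochRecord, SAMPLES_PER_RAW_EPOCH

logger = logging.getLogger(__name__)

EPOCH_RATE_HZ = 64
SAMPLES_PER_EPOCH = 256
DOWNSAMPLE_FACTOR = 4


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth high-pass used on the EMG channel."""

    cutoff_hz: float = 0.5
    order: int = 4

    def __post_init__(self):
        if not 0 < self.cutoff_hz < EPOCH_RATE_HZ / 2:
            raise ValueError("cutoff must lie below the 32 Hz Nyquist of the 64 Hz epoch")


@dataclass
class EpochDataset:
    """Preprocessed model input: (N, 256, 2) signals and (N, 3) one-hot labels.

    Channel 0 is EEG, channel 1 is EMG; axis order is (epoch, time, channel).
    """

    signals: np.ndarray
    labels: np.ndarray
    epoch_rate_hz: float = EPOCH_RATE_HZ
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.signals.ndim != 3 or self.signals.shape[1:] != (SAMPLES_PER_EPOCH, 2):
            raise ValueError(f"signals must be (N, {SAMPLES_PER_EPOCH}, 2)")
        if self.labels.shape != (self.signals.shape[0], 3):
            raise ValueError("labels must be (N, 3)")
        if np.any(self.labels.sum(axis=1) != 1):
            raise ValueError("labels must be strict one-hot (artifacts removed upstream)")
        if not np.isfinite(self.signals).all():
            raise ValueError("non-finite signal values")

    def __len__(self) -> int:
        return self.signals.shape[0]

    @property
    def stage_indices(self) -> np.ndarray:
        """Integer class per epoch: 0=W, 1=N, 2=R."""
        return self.labels.argmax(axis=1)


def downsample_epoch(series: np.ndarray) -> np.ndarray:
    """Fourfold polyphase anti-aliased downsampling of one 1024-sample channel."""
    series = np.asarray(series, dtype=float)
    if series.size != SAMPLES_PER_RAW_EPOCH:
        raise ValueError(f"expected {SAMPLES_PER_RAW_EPOCH} samples, got {series.size}")
    out = signal.resample_poly(series, 1, DOWNSAMPLE_FACTOR)
    assert out.size == SAMPLES_PER_EPOCH
    return out


def highpass_emg(emg: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """0.5 Hz high-pass on the 64 Hz EMG, applied forward-backward (zero phase)."""
    emg = np.asarray(emg, dtype=float)
    if not np.isfinite(emg).all():
        raise ValueError("non-finite EMG input")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass",
                        fs=EPOCH_RATE_HZ, output="sos")
    return signal.sosfiltfilt(sos, emg)


def baseline_correct(series: np.ndarray) -> np.ndarray:
    """Subtract the per-epoch mean so each epoch is centred on zero volts."""
    series = np.asarray(series, dtype=float)
    return series - series.mean()


def remove_artifact_epochs(epochs: Sequence[EpochRecord]) -> list[EpochRecord]:
    """Drop all and only A-labelled epochs, preserving order."""
    kept = [ep for ep in epochs if not ep.label.is_artifact]
    n_dropped = len(epochs) - len(kept)
    if n_dropped:
        logger.info("discarded %d artifact epoch(s) of %d", n_dropped, len(epochs))
    if epochs and not kept:
        warnings.warn("all epochs were artifacts; dataset is empty", stacklevel=2)
    return kept


def preprocess_dataset(epochs: Sequence[EpochRecord],
                       filter_spec: FilterSpec = FilterSpec()) -> EpochDataset:
    """Run the full per-epoch chain and assemble the (N, 256, 2) input tensor.

    Both channels are downsampled and baseline-corrected; only the EMG is
    high-pass filtered (low-frequency EEG content, e.g. NREM delta, must
    survive).
    """
    kept = remove_artifact_epochs(epochs)
    n = len(kept)
    signals = np.empty((n, SAMPLES_PER_EPOCH, 2))
    labels = np.empty((n, 3))
    provenance = []
    for i, ep in enumerate(kept):
        eeg = downsample_epoch(ep.eeg)
        emg = highpass_emg(downsample_epoch(ep.emg), filter_spec)
        signals[i, :, 0] = baseline_correct(eeg)
        signals[i, :, 1] = baseline_correct(emg)
        labels[i] = ep.label.onehot
        provenance.append(f"{ep.source_id}:{ep.index}")
    return EpochDataset(signals=signals, labels=labels, provenance=provenance)


def save_dataset(path, ds: EpochDataset) -> None:
    """Cache a preprocessed dataset as a compressed array archive (.npz)."""
    np.savez_compressed(path, signals=ds.signals, labels=ds.labels,
                        provenance=np.array(ds.provenance, dtype=object))


def load_dataset(path) -> EpochDataset:
    with np.load(path, allow_pickle=True) as f:
        return EpochDataset(signals=f["signals"], labels=f["labels"],
                            provenance=list(f["provenance"]))


def welch_psd(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density; returns (frequencies, powers)."""
    series = np.asarray(series, dtype=float)
    if series.size < 64:
        raise ValueError("series too short for a PSD estimate (need >= 64 samples)")
    nperseg = min(256, series.size)
    freqs, power = signal.welch(series, fs=fs, nperseg=nperseg)
    return freqs, power


def band_power_fraction(series: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Fraction of total Welch power in [lo, hi) Hz. Used for stage diagnostics."""
    freqs, power = welch_psd(series, fs)
    total = power.sum()
    if total == 0:
        return 0.0
    mask = (freqs >= lo) & (freqs < hi)
    return float(power[mask].sum() / total)
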