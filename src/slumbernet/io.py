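"""Reading, validating and epoching paired voltage/stage-label files.

Recordings arrive as delimited text tables with exactly two float
columns (EEG, EMG) sampled at a caller-declared rate, and a matching
label file with one stage token per line. Scoring epochs are 4 s long:
1024 samples per channel at 256 Hz.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

EPOCH_SECONDS = 4
MODEL_INPUT_RATE_HZ = 256
SAMPLES_PER_RAW_EPOCH = EPOCH_SECONDS * MODEL_INPUT_RATE_HZ  # 1024

#: One-hot codes for the three vigilance states plus the artifact flag.
#: Artifact epochs carry the all-ones code and never reach training.
ONEHOT = {
    "W": (1, 0, 0),
    "N": (0, 1, 0),
    "R": (0, 0, 1),
    "A": (1, 1, 1),
}
STAGES = ("W", "N", "R")


class FormatRejectionError(ValueError):
    """Raised when a voltage table violates the two-float-column contract."""


class AlignmentError(ValueError):
    """Raised when sample count and label count disagree by more than one epoch."""


@dataclass(frozen=True)
class StageLabel:
    """A single epoch's vigilance-state label."""

    code: str  # one of W, N, R, A

    def __post_init__(self):
        if self.code not in ONEHOT:
            raise ValueError(f"unknown stage code {self.code!r}")

    @property
    def onehot(self) -> np.ndarray:
        return np.array(ONEHOT[self.code], dtype=float)

    @property
    def is_artifact(self) -> bool:
        return self.code == "A"


@dataclass
class RawRecording:
    """Equal-length EEG and EMG voltage series (µV) at a known rate."""

    eeg: np.ndarray
    emg: np.ndarray
    sample_rate_hz: float
    source_id: str = ""

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D series of identical length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not (np.isfinite(self.eeg).all() and np.isfinite(self.emg).all()):
            raise ValueError("non-finite samples in recording")

    def __len__(self) -> int:
        return self.eeg.size


@dataclass
class EpochRecord:
    """One 4-s scoring epoch: 1024 raw samples per channel at 256 Hz."""

    eeg: np.ndarray
    emg: np.ndarray
    label: StageLabel
    index: int
    source_id: str = ""
    duration_s: float = EPOCH_SECONDS

    def __post_init__(self):
        if self.eeg.size != SAMPLES_PER_RAW_EPOCH or self.emg.size != SAMPLES_PER_RAW_EPOCH:
            raise ValueError(
                f"epoch must hold exactly {SAMPLES_PER_RAW_EPOCH} samples per channel"
            )


def read_voltage_table(path, sample_rate_hz: float, source_id: str | None = None) -> RawRecording:
    """Read a two-column delimited float table into a :class:`RawRecording`.

    The delimiter (comma or tab/whitespace) is autodetected, and a single
    non-numeric header line is skipped. Files with anything other than two
    numeric columns are rejected, with the offending line named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatRejectionError(f"{path}: empty voltage table")

    sep = "," if "," in lines[0] else r"\s+"
    skip = 0
    first = [t for t in lines[0].replace(",", " ").split()]
    if not all(_is_number(t) for t in first):
        skip = 1

    for lineno, ln in enumerate(lines[skip:], start=skip + 1):
        tokens = ln.replace(",", " ").split()
        if len(tokens) != 2:
            raise FormatRejectionError(
                f"{path}: line {lineno} has {len(tokens)} value columns, expected 2"
            )
        if not all(_is_number(t) for t in tokens):
            raise FormatRejectionError(f"{path}: non-numeric cell on line {lineno}")

    df = pd.read_csv(
        _io.StringIO("\n".join(lines[skip:])), sep=sep, header=None, engine="python"
    )
    return RawRecording(
        eeg=df.iloc[:, 0].to_numpy(float),
        emg=df.iloc[:, 1].to_numpy(float),
        sample_rate_hz=sample_rate_hz,
        source_id=source_id or path.stem,
    )


def write_voltage_table(path, rec: RawRecording) -> None:
    """Write a recording as the same two-column CSV ``read_voltage_table`` reads."""
    pd.DataFrame({"eeg": rec.eeg, "emg": rec.emg}).to_csv(
        path, index=False, header=False, float_format="%.9g"
    )


def parse_stage_labels(path) -> list[StageLabel]:
    """Parse a per-epoch label file: first token of each non-empty line.

    W/N/R map to their one-hot codes; every other token is an artifact (A).
    """
    path = Path(path)
    labels = []
    for ln in path.read_text().splitlines():
        tokens = ln.split()
        if not tokens:
            continue
        tok = tokens[0]
        labels.append(StageLabel(tok if tok in STAGES else "A"))
    return labels


def write_stage_labels(path, labels: Sequence[StageLabel]) -> None:
    Path(path).write_text("".join(f"{lab.code}\n" for lab in labels))


def resample_recording(rec: RawRecording, target_hz: float) -> RawRecording:
    """Polyphase rational-ratio resampling (e.g. 500 Hz -> 256 Hz uses 64/125)."""
    if target_hz > rec.sample_rate_hz:
        raise ValueError("target rate must not exceed the source rate")
    if target_hz == rec.sample_rate_hz:
        return RawRecording(rec.eeg.copy(), rec.emg.copy(), rec.sample_rate_hz, rec.source_id)
    frac = Fraction(target_hz / rec.sample_rate_hz).limit_denominator(10000)
    if abs(float(frac) - target_hz / rec.sample_rate_hz) > 1e-9:
        raise ValueError(
            f"rate ratio {target_hz}/{rec.sample_rate_hz} is not expressible "
            "as a small rational within tolerance"
        )
    eeg = resample_poly(rec.eeg, frac.numerator, frac.denominator)
    emg = resample_poly(rec.emg, frac.numerator, frac.denominator)
    return RawRecording(eeg, emg, target_hz, rec.source_id)


def segment_into_epochs(rec: RawRecording, labels: Sequence[StageLabel]) -> list[EpochRecord]:
    """Cut a 256 Hz recording into labelled 1024-sample epochs.

    Epoch i spans samples [1024*i, 1024*(i+1)) (0-based, half-open). A
    trailing partial epoch is dropped, and a mismatch of at most one epoch
    between floor(len/1024) and the label count is absorbed; anything larger
    is an alignment error.
    """
    if rec.sample_rate_hz != MODEL_INPUT_RATE_HZ:
        raise ValueError(f"recording must be at {MODEL_INPUT_RATE_HZ} Hz; resample first")
    if len(rec) < SAMPLES_PER_RAW_EPOCH:
        raise ValueError("recording shorter than one epoch")
    if not labels:
        raise ValueError("labels must be non-empty")
    n_from_samples = len(rec) // SAMPLES_PER_RAW_EPOCH
    if abs(n_from_samples - len(labels)) > 1:
        raise AlignmentError(
            f"sample count implies {n_from_samples} epochs but {len(labels)} labels given"
        )
    n = min(n_from_samples, len(labels))
    out = []
    for i in range(n):
        s = slice(i * SAMPLES_PER_RAW_EPOCH, (i + 1) * SAMPLES_PER_RAW_EPOCH)
        out.append(EpochRecord(rec.eeg[s], rec.emg[s], labels[i], index=i,
                               source_id=rec.source_id))
    return out


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
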