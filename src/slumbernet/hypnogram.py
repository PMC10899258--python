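"""Scoring new recordings: hypnograms, 2-h stage-minute bins, concordance.

A hypnogram is the time-ordered sequence of predicted stages, one per
4-s epoch, with the softmax probability triple retained. Hypnograms bin
into minutes of each stage per 2-h window (1800 epochs), and binned
true-vs-predicted series are compared with Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    EpochRecord,
    RawRecording,
    StageLabel,
    STAGES,
    SAMPLES_PER_RAW_EPOCH,
    read_voltage_table,
    resample_recording,
)
from .metrics import confusion_matrix, stage_metrics_row
from .nn import Network
from .preprocess import preprocess_dataset

EPOCHS_PER_HOUR = 900  # 3600 s / 4 s


@dataclass
class Hypnogram:
    stages: list[str]          # predicted stage per epoch, in {W, N, R}
    probabilities: np.ndarray  # (N, 3) softmax outputs
    start_s: np.ndarray        # epoch onset, seconds from recording start

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.start_s = np.asarray(self.start_s, dtype=float)
        n = len(self.stages)
        if self.probabilities.shape != (n, 3) or self.start_s.shape != (n,):
            raise ValueError("inconsistent hypnogram field lengths")
        if any(s not in STAGES for s in self.stages):
            raise ValueError("hypnogram stages must be W, N or R")

    def __len__(self) -> int:
        return len(self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_index": np.arange(len(self)),
            "start_s": self.start_s,
            "stage": self.stages,
            "p_wake": self.probabilities[:, 0],
            "p_nrem": self.probabilities[:, 1],
            "p_rem": self.probabilities[:, 2],
        })


def preprocess_recording_for_scoring(rec: RawRecording):
    """Epoch and preprocess a recording without labels (inference path)."""
    if rec.sample_rate_hz != 256:
        rec = resample_recording(rec, 256)
    n = len(rec) // SAMPLES_PER_RAW_EPOCH
    if n == 0:
        raise ValueError("recording shorter than one 4-s epoch")
    placeholder = StageLabel("W")  # labels unknown at inference; never used
    epochs = [
        EpochRecord(rec.eeg[i * SAMPLES_PER_RAW_EPOCH:(i + 1) * SAMPLES_PER_RAW_EPOCH],
                    rec.emg[i * SAMPLES_PER_RAW_EPOCH:(i + 1) * SAMPLES_PER_RAW_EPOCH],
                    placeholder, index=i, source_id=rec.source_id)
        for i in range(n)
    ]
    return preprocess_dataset(epochs)


def score_recording(model: Network, voltage_path_or_rec,
                    sample_rate_hz: float = 256,
                    batch_size: int = 256) -> Hypnogram:
    """Preprocess (no augmentation), run the model, argmax each epoch.

    Ties break toward the earlier class in (W, N, R) order, which is the
    behaviour of argmax over that fixed ordering.
    """
    if isinstance(voltage_path_or_rec, RawRecording):
        rec = voltage_path_or_rec
    else:
        rec = read_voltage_table(voltage_path_or_rec, sample_rate_hz)
    ds = preprocess_recording_for_scoring(rec)
    probs = model.predict_proba(ds.signals[..., None], batch_size=batch_size)
    pred = probs.argmax(axis=1)
    return Hypnogram(
        stages=[STAGES[i] for i in pred],
        probabilities=probs,
        start_s=4.0 * np.arange(len(pred)),
    )


def hypnogram_from_labels(labels) -> Hypnogram:
    """Build a reference hypnogram from manual stage labels (artifacts excluded)."""
    kept = [(i, lab) for i, lab in enumerate(labels) if not lab.is_artifact]
    stages = [lab.code for _, lab in kept]
    probs = np.stack([lab.onehot for _, lab in kept])
    start = 4.0 * np.array([i for i, _ in kept], dtype=float)
    return Hypnogram(stages=stages, probabilities=probs, start_s=start)


def bin_hypnogram(h: Hypnogram, bin_hours: float = 2.0) -> pd.DataFrame:
    """Minutes of each stage per bin; a trailing partial bin is flagged.

    Columns: bin_start_h, wake_min, nrem_min, rem_min, full. Full-bin rows
    sum to 60 * bin_hours minutes.
    """
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    per_bin = int(round(bin_hours * EPOCHS_PER_HOUR))
    bin_ix = (h.start_s // (bin_hours * 3600.0)).astype(int)
    stage_ix = np.array([STAGES.index(s) for s in h.stages])
    rows = []
    for b in range(bin_ix.max() + 1):
        mask = bin_ix == b
        counts = np.bincount(stage_ix[mask], minlength=3)
        rows.append({
            "bin_start_h": b * bin_hours,
            "wake_min": counts[0] * 4.0 / 60.0,
            "nrem_min": counts[1] * 4.0 / 60.0,
            "rem_min": counts[2] * 4.0 / 60.0,
            "full": int(mask.sum()) == per_bin,
        })
    return pd.DataFrame(rows)


def concordance(true_bins: pd.DataFrame, pred_bins: pd.DataFrame,
                include_partial: bool = False) -> pd.DataFrame:
    """Pearson r (and p) between true and predicted minutes, per stage and pooled.

    Partial trailing bins are excluded by default; a zero-variance series
    yields r = NaN with a note rather than an error.
    """
    if len(true_bins) != len(pred_bins):
        raise ValueError("bin grids differ in length")
    keep = np.ones(len(true_bins), dtype=bool)
    if not include_partial:
        keep = true_bins["full"].to_numpy() & pred_bins["full"].to_numpy()
    cols = ["wake_min", "nrem_min", "rem_min"]
    rows = []
    pooled_t, pooled_p = [], []
    for stage, col in zip(STAGES, cols):
        t = true_bins.loc[keep, col].to_numpy()
        p = pred_bins.loc[keep, col].to_numpy()
        pooled_t.append(t)
        pooled_p.append(p)
        rows.append({"stage": stage, **_pearson(t, p)})
    rows.append({"stage": "pooled",
                 **_pearson(np.concatenate(pooled_t), np.concatenate(pooled_p))})
    return pd.DataFrame(rows)


def epoch_level_metrics(true_stages, pred_stages) -> dict[str, float]:
    """Per-stage metric row for manually-vs-model scored epoch sequences."""
    cm = confusion_matrix(true_stages, pred_stages)
    return stage_metrics_row(cm)


def _pearson(x: np.ndarray, y: np.ndarray) -> dict:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "p_value": float("nan"), "n_bins": len(x),
                "note": "undefined (zero variance or <2 bins)"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n_bins": len(x), "note": ""}
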