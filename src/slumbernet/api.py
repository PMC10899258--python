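"""Model/Results facade over the training pipeline.

``SleepStageClassifier`` is constructed from a preprocessed
:class:`~slumbernet.preprocess.EpochDataset` (or raw signal/label
arrays); ``fit()`` runs the published optimization protocol and returns
a ``SleepScoringResults`` carrying the fitted network, its training
history, held-out diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .hypnogram import Hypnogram, score_recording
from .io import STAGES
from .model import ModelConfig, count_trainable_parameters
from .nn import Network
from .preprocess import EpochDataset
from .training import TrainHistory, cross_validate, evaluate_model, train_final


class SleepStageClassifier:
    """Residual-network classifier of 4-s EEG/EMG epochs into W/N/R."""

    def __init__(self, data: EpochDataset, config: ModelConfig = ModelConfig(),
                 augment: AugmentConfig | None = AugmentConfig()):
        self.data = data
        self.config = config
        self.augment = augment

    @classmethod
    def from_arrays(cls, signals: np.ndarray, labels: np.ndarray, **kw
                    ) -> "SleepStageClassifier":
        return cls(EpochDataset(signals=signals, labels=labels), **kw)

    def fit(self, monitor_fraction: float = 0.2) -> "SleepScoringResults":
        """Train on all data with an internal stratified monitor split."""
        model, hist = train_final(self.data, self.config, self.augment,
                                  monitor_fraction=monitor_fraction)
        return SleepScoringResults(model, hist, self)

    def cross_validate(self, k: int = 5, seed: int = 0) -> pd.DataFrame:
        """Stratified k-fold table of per-stage metrics with mean/SEM rows."""
        return cross_validate(self.data, self.config, self.augment, k=k, seed=seed)


class SleepScoringResults:
    """Fitted network plus training diagnostics."""

    def __init__(self, model: Network, history: TrainHistory,
                 classifier: SleepStageClassifier):
        self.model = model
        self.history = history
        self.classifier = classifier

    def predict_proba(self, signals: np.ndarray) -> np.ndarray:
        """(N, 3) stage probabilities for (N, 256, 2) preprocessed epochs."""
        return self.model.predict_proba(np.asarray(signals)[..., None],
                                        batch_size=self.classifier.config.batch_size)

    def predict(self, signals: np.ndarray) -> np.ndarray:
        """Integer stage per epoch (0=W, 1=N, 2=R); ties break toward W."""
        return self.predict_proba(signals).argmax(axis=1)

    def predict_stages(self, signals: np.ndarray) -> list[str]:
        return [STAGES[i] for i in self.predict(signals)]

    def score_recording(self, voltage_path_or_rec, sample_rate_hz: float = 256
                        ) -> Hypnogram:
        return score_recording(self.model, voltage_path_or_rec, sample_rate_hz)

    def evaluate(self, data: EpochDataset | None = None) -> dict[str, float]:
        return evaluate_model(self.model, data or self.classifier.data)

    def summary(self) -> str:
        cfg = self.classifier.config
        h = self.history
        lines = [
            "Sleep-stage residual network — fit summary",
            "=" * 46,
            f"{'epochs in dataset':<28}{len(self.classifier.data):>14}",
            f"{'residual blocks':<28}{cfg.n_resnet_blocks:>14}",
            f"{'feature maps (first block)':<28}{cfg.n_feature_maps:>14}",
            f"{'trainable parameters':<28}{count_trainable_parameters(self.model):>14}",
            f"{'optimizer':<28}{cfg.optimizer_name:>14}",
            f"{'learning rate (initial)':<28}{cfg.learning_rate:>14.2e}",
            f"{'batch size':<28}{cfg.batch_size:>14}",
            f"{'training passes':<28}{len(h.train_loss):>14}",
            "-" * 46,
            f"{'final training loss':<28}{h.train_loss[-1]:>14.4f}",
            f"{'final training accuracy':<28}{h.train_accuracy[-1]:>14.4f}",
            f"{'final validation loss':<28}{h.val_loss[-1]:>14.4f}",
            f"{'final validation accuracy':<28}{h.val_accuracy[-1]:>14.4f}",
            f"{'best (lowest-loss) epoch':<28}{h.best_epoch + 1:>14}",
            "=" * 46,
        ]
        return "\n".join(lines)
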