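"""Training-time stochastic augmentation of preprocessed epochs.

Three transforms, composed scale -> translate -> noise with fresh draws
on every pass: per-channel amplitude scaling with independent factors
for EEG and EMG; a circular time shift drawn once and applied to both
channels so they stay temporally yoked; and additive zero-mean Gaussian
noise scaled to a fraction of each channel's standard deviation. Labels
are never touched and validation data is never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AugmentConfig:
    amp_scale_range: tuple[float, float] = (0.8, 1.2)
    max_shift: int = 64          # samples of 256 (one second at 64 Hz)
    noise_sigma: float = 0.05    # fraction of per-channel SD
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.amp_scale_range
        if not 0 < lo <= hi:
            raise ValueError("amp_scale_range must be positive and ordered")
        if not 0 <= self.max_shift < 256:
            raise ValueError("max_shift must be in [0, 256)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def scale_amplitude(epoch: np.ndarray, rng: np.random.Generator,
                    cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Multiply each channel by an independent draw from amp_scale_range."""
    lo, hi = cfg.amp_scale_range
    factors = rng.uniform(lo, hi, size=epoch.shape[-1])
    return epoch * factors


def translate_jointly(epoch: np.ndarray, rng: np.random.Generator,
                      cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Circularly roll both channels by one shared shift in [-max_shift, max_shift]."""
    if cfg.max_shift == 0:
        return epoch.copy()
    s = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
    return np.roll(epoch, s, axis=0)


def add_noise(epoch: np.ndarray, rng: np.random.Generator,
              cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Add zero-mean Gaussian noise with SD = noise_sigma x per-channel SD."""
    if cfg.noise_sigma == 0:
        return epoch.copy()
    sd = epoch.std(axis=0, keepdims=True)
    return epoch + rng.normal(0.0, 1.0, size=epoch.shape) * (cfg.noise_sigma * sd)


def augment_epoch(epoch: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    return add_noise(translate_jointly(scale_amplitude(epoch, rng, cfg), rng, cfg), rng, cfg)


def augment_batch(batch: np.ndarray, labels: np.ndarray,
                  cfg: AugmentConfig = AugmentConfig(),
                  training: bool = True,
                  rng: np.random.Generator | None = None):
    """Augment a (B, 256, 2) batch; bit-identical passthrough when not training."""
    if batch.shape[0] != labels.shape[0]:
        raise ValueError("batch and labels disagree in length")
    if not training:
        return batch, labels
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = np.empty_like(batch)
    for i in range(batch.shape[0]):
        out[i] = augment_epoch(batch[i], rng, cfg)
    return out, labels
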