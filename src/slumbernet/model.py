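"""The residual sleep-scoring architecture and its configuration.

Seven residual blocks over a (256, 2, 1) input — 256 time samples, two
signals (EEG, EMG), one feature map — with the feature-map count
doubling per block (8, 16, ..., 512), then global average pooling and a
three-way softmax head yielding Wake/NREM/REM probabilities.

The convolution kernel spans 2 steps along the time axis and 1 along
the signal axis by default; ``kernel_orientation="signal"`` transposes
it for the alternative reading of the published kernel shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .nn import Conv2D, Network, ResidualBlock

INPUT_SHAPE = (256, 2, 1)


@dataclass(frozen=True)
class ModelConfig:
    """Published training/architecture hyperparameters, defaulted exactly."""

    num_epochs: int = 50
    learning_rate: float = 1e-6
    batch_size: int = 128
    optimizer_name: str = "Adam"
    n_resnet_blocks: int = 7
    n_feature_maps: int = 8
    kernel: tuple[int, int] = (2, 1)          # (time, signal) extents
    strides: tuple[int, int] = (1, 1)
    dropout_rate: float = 0.0
    n_classes: int = 3
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    kernel_orientation: str = "time"           # "time" (2,1) | "signal" (1,2)
    seed: int = 0

    def __post_init__(self):
        if self.kernel_orientation not in ("time", "signal"):
            raise ValueError("kernel_orientation must be 'time' or 'signal'")
        if self.strides != (1, 1):
            raise ValueError("only stride (1,1) is supported (shapes must match the shortcut)")
        if self.n_resnet_blocks < 1 or self.n_feature_maps < 1:
            raise ValueError("block and feature-map counts must be positive")

    @property
    def effective_kernel(self) -> tuple[int, int]:
        return self.kernel if self.kernel_orientation == "time" else self.kernel[::-1]

    @property
    def block_widths(self) -> list[int]:
        """Feature maps per block: doubling from ``n_feature_maps``."""
        return [self.n_feature_maps * 2 ** i for i in range(self.n_resnet_blocks)]

    def scaled(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    @classmethod
    def reduced(cls, seed: int = 0) -> "ModelConfig":
        """CPU-scale configuration for synthetic-data experiments.

        Two blocks starting at 4 maps, learning rate raised to 1e-4 and ten
        training passes; batch 8 so the optimizer takes enough steps on a
        few-thousand-epoch dataset.
        """
        return cls(n_resnet_blocks=2, n_feature_maps=4, learning_rate=1e-4,
                   num_epochs=10, batch_size=8, seed=seed)


@dataclass(frozen=True)
class ResBlockSpec:
    in_maps: int
    out_maps: int
    kernel: tuple[int, int] = (2, 1)
    dropout_rate: float = 0.0


def build_block(spec: ResBlockSpec, rng=None) -> ResidualBlock:
    """One residual block from its spec; projection shortcut iff widths differ."""
    if spec.in_maps < 1 or spec.out_maps < 1:
        raise ValueError("map counts must be positive")
    return ResidualBlock(spec.in_maps, spec.out_maps, spec.kernel,
                         spec.dropout_rate, rng)


def build_model(cfg: ModelConfig = ModelConfig()) -> Network:
    """Stack the residual blocks, pool, and attach the 3-way softmax head."""
    rng = np.random.default_rng(cfg.seed)
    widths = cfg.block_widths
    blocks = []
    in_maps = cfg.input_shape[2]
    for w in widths:
        blocks.append(build_block(
            ResBlockSpec(in_maps, w, cfg.effective_kernel, cfg.dropout_rate), rng))
        in_maps = w
    return Network(blocks, head_in=widths[-1], n_classes=cfg.n_classes, rng=rng)


def forward(model: Network, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities for a (B, 256, 2, 1) batch."""
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 4:
        raise ValueError("batch must be 4-D: (B, time, signal, maps)")
    return model.forward(batch, training=False)


def count_trainable_parameters(model: Network) -> int:
    return sum(layer.n_trainable for layer in model.layers())


def count_non_trainable_parameters(model: Network) -> int:
    return sum(layer.n_non_trainable for layer in model.layers())


def summarize(model: Network) -> str:
    """Per-layer text summary (name, parameter counts) plus totals."""
    lines = [f"{'layer':<28}{'trainable':>12}{'non-trainable':>16}"]
    for i, layer in enumerate(model.layers()):
        name = type(layer).__name__
        if isinstance(layer, Conv2D):
            name += f"({layer.in_maps}->{layer.out_maps}, k={layer.kt}x{layer.ks})"
        lines.append(f"{i:>3} {name:<24}{layer.n_trainable:>12}{layer.n_non_trainable:>16}")
    lines.append(f"{'total':<28}{count_trainable_parameters(model):>12}"
                 f"{count_non_trainable_parameters(model):>16}")
    return "\n".join(lines)


def save_checkpoint(path, model: Network, cfg: ModelConfig, extra: dict | None = None) -> None:
    """Weights as .npz next to a .json config/manifest."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.get_weights())
    meta = {"config": _cfg_to_json(cfg)}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[Network, ModelConfig, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = _cfg_from_json(meta["config"])
    model = build_model(cfg)
    with np.load(path.with_suffix(".npz")) as f:
        model.set_weights({k: f[k] for k in f.files})
    return model, cfg, meta


def _cfg_to_json(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    for k in ("kernel", "strides", "input_shape"):
        d[k] = list(d[k])
    return d


def _cfg_from_json(d: dict) -> ModelConfig:
    d = dict(d)
    for k in ("kernel", "strides", "input_shape"):
        d[k] = tuple(d[k])
    return ModelConfig(**d)
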