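"""Minimal NumPy neural-network engine for the residual classifier.

Implements exactly the layers the sleep-scoring architecture needs —
2-D convolution at stride (1,1) with "same" padding, batch
normalization, ReLU, dropout, global average pooling, a dense softmax
head — with hand-derived backward passes and an Adam optimizer. Arrays
are laid out channels-last: (batch, time, signal, feature_maps), i.e.
the (256, 2, 1) model input plus a batch axis.

Each layer exposes ``params`` / ``grads`` (aligned lists of arrays),
``forward(x, training)`` and ``backward(dy)``. Gradients for every layer
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless by default, no parameters."""

    params: list  # np.ndarray entries, updated in place by the optimizer
    grads: list   # same shapes/order as params

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params))

    @property
    def n_non_trainable(self) -> int:
        return 0


class Conv2D(Layer):
    """Stride-(1,1), "same"-padded 2-D convolution over (time, signal) axes.

    For a kernel extent k the total padding is k-1, split floor((k-1)/2)
    before and the remainder after (the TensorFlow "same" convention, so
    an even kernel pads one sample at the end).
    """

    def __init__(self, in_maps: int, out_maps: int, kernel=(2, 1), rng=None):
        super().__init__()
        self.kt, self.ks = kernel
        self.in_maps, self.out_maps = in_maps, out_maps
        rng = rng or np.random.default_rng(0)
        fan_in = self.kt * self.ks * in_maps
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(self.kt, self.ks, in_maps, out_maps))
        b = np.zeros(out_maps)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _pad(self):
        pt0 = (self.kt - 1) // 2
        ps0 = (self.ks - 1) // 2
        return pt0, self.kt - 1 - pt0, ps0, self.ks - 1 - ps0

    def forward(self, x, training=False):
        w, b = self.params
        pt0, pt1, ps0, ps1 = self._pad()
        xp = np.pad(x, ((0, 0), (pt0, pt1), (ps0, ps1), (0, 0)))
        self._xp = xp
        B, T, S, _ = x.shape
        y = np.empty((B, T, S, self.out_maps))
        y[:] = b
        for a in range(self.kt):
            for c in range(self.ks):
                y += np.einsum("btsi,io->btso", xp[:, a:a + T, c:c + S, :], w[a, c])
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        w, _ = self.params
        B, T, S, _ = self._in_shape
        xp = self._xp
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for a in range(self.kt):
            for c in range(self.ks):
                dw[a, c] = np.einsum("btsi,btso->io", xp[:, a:a + T, c:c + S, :], dy)
                dxp[:, a:a + T, c:c + S, :] += np.einsum("btso,io->btsi", dy, w[a, c])
        self.grads[0][:] = dw
        self.grads[1][:] = dy.sum(axis=(0, 1, 2))
        pt0, pt1, ps0, ps1 = self._pad()
        return dxp[:, pt0:pt0 + T, ps0:ps0 + S, :]


class BatchNorm(Layer):
    """Per-feature-map batch normalization over the (batch, time, signal) axes."""

    def __init__(self, n_maps: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(n_maps)
        beta = np.zeros(n_maps)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    @property
    def n_non_trainable(self) -> int:
        return self.running_mean.size + self.running_var.size

    def forward(self, x, training=False):
        gamma, beta = self.params
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            self._ivar = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._ivar
            self._n = x.shape[0] * x.shape[1] * x.shape[2]
            return gamma * self._xhat + beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return gamma * xhat + beta

    def backward(self, dy):
        gamma, _ = self.params
        xhat, ivar, n = self._xhat, self._ivar, self._n
        self.grads[0][:] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads[1][:] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * gamma
        # standard batch-norm gradient with batch statistics
        dx = (ivar / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; inert at rate 0 (the published configuration)."""

    def __init__(self, rate: float = 0.0, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if training and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAveragePool(Layer):
    """Mean over the time and signal axes: (B, T, S, C) -> (B, C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        B, T, S, C = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (T * S)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        b = np.zeros(out_features)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training=False):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy):
        w, _ = self.params
        self.grads[0][:] = self._x.T @ dy
        self.grads[1][:] = dy.sum(axis=0)
        return dy @ w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


class ResidualBlock(Layer):
    """[conv-BN-dropout-ReLU] x2 then conv-BN, merged with a shortcut.

    The shortcut is the identity when the map counts match, otherwise a
    1x1 projection convolution with its own batch norm; the merge is an
    elementwise add followed by ReLU.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel=(2, 1),
                 dropout_rate: float = 0.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_maps, self.out_maps = in_maps, out_maps
        self.body = [
            Conv2D(in_maps, out_maps, kernel, rng), BatchNorm(out_maps),
            Dropout(dropout_rate, rng), ReLU(),
            Conv2D(out_maps, out_maps, kernel, rng), BatchNorm(out_maps),
            Dropout(dropout_rate, rng), ReLU(),
            Conv2D(out_maps, out_maps, kernel, rng), BatchNorm(out_maps),
        ]
        if in_maps != out_maps:
            self.shortcut = [Conv2D(in_maps, out_maps, (1, 1), rng), BatchNorm(out_maps)]
        else:
            self.shortcut = []  # identity
        self._merge_relu = ReLU()

    @property
    def has_projection(self) -> bool:
        return bool(self.shortcut)

    def layers(self):
        return self.body + self.shortcut

    def forward(self, x, training=False):
        h = x
        for layer in self.body:
            h = layer.forward(h, training)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, training)
        return self._merge_relu.forward(h + s, training)

    def backward(self, dy):
        d = self._merge_relu.backward(dy)
        dh = d
        for layer in reversed(self.body):
            dh = layer.backward(dh)
        ds = d
        for layer in reversed(self.shortcut):
            ds = layer.backward(ds)
        return dh + ds


class Network:
    """A stack of residual blocks plus pooling and a softmax head."""

    def __init__(self, blocks: list[ResidualBlock], head_in: int, n_classes: int, rng=None):
        self.blocks = blocks
        self.pool = GlobalAveragePool()
        self.dense = Dense(head_in, n_classes, rng)
        self._calibrate_head_bias(rng or np.random.default_rng(0))

    def _calibrate_head_bias(self, rng, n_probe: int = 8, t_probe: int = 256) -> None:
        """Center the initial logits on a seeded random probe batch.

        Pooled backbone features are positive-mean (post-ReLU), so random
        head weights alone would bias a fresh network hard toward one
        class. Setting the head bias to minus the mean probe logit keeps
        the variance-scaled weights (and their gradient flow) while a
        freshly built network emits near-uniform class probabilities.
        """
        in_maps = self.blocks[0].in_maps
        x = rng.standard_normal((n_probe, t_probe, 2, in_maps))
        h = x
        for b in self.blocks:
            h = b.forward(h, training=False)
        f_mean = self.pool.forward(h, training=False).mean(axis=0)
        w, bias = self.dense.params
        bias[:] = -(f_mean @ w)

    # -- structure ---------------------------------------------------------
    def layers(self):
        out = []
        for b in self.blocks:
            out.extend(b.layers())
        out.extend([self.pool, self.dense])
        return out

    def parameters(self):
        ps, gs = [], []
        for layer in self.layers():
            ps.extend(layer.params)
            gs.extend(layer.grads)
        return ps, gs

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Probabilities of shape (B, n_classes); rows sum to 1."""
        h = np.asarray(x, dtype=float)
        for b in self.blocks:
            h = b.forward(h, training)
        h = self.pool.forward(h, training)
        logits = self.dense.forward(h, training)
        self._probs = softmax(logits)
        return self._probs

    def loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        """Training-mode forward + full backward; grads left in the layers."""
        probs = self.forward(x, training=True)
        loss = cross_entropy(probs, y_onehot)
        dlogits = (probs - y_onehot) / x.shape[0]
        d = self.dense.backward(dlogits)
        d = self.pool.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size], training=False))
        return np.concatenate(out, axis=0)

    # -- serialization -----------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_param{j}"] = p.copy()
            if isinstance(layer, BatchNorm):
                state[f"layer{i}_running_mean"] = layer.running_mean.copy()
                state[f"layer{i}_running_var"] = layer.running_var.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for j, p in enumerate(layer.params):
                p[:] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"layer{i}_running_mean"].copy()
                layer.running_var = state[f"layer{i}_running_var"].copy()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list, lr: float = 1e-6,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
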