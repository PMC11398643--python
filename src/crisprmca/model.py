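"""The CRISPR-MCA network.

Pipeline (input is the 24x7 encoded guide/target matrix):

    multi-scale convolution block -> layer normalization -> + sinusoidal
    positional encoding -> 8-head self-attention -> additive skip
    connection -> flatten -> dense 256 (ReLU, dropout) -> dense 128
    (ReLU, dropout) -> dense 2 (softmax)

The convolution block has four parallel branches (1x1; 1x1 -> 3; 1x1 -> 5;
max-pool 3 -> 1x1), concatenated over channels, so local and wider base
context are extracted at several scales while the attention stage relates
positions across the whole pair.  Ablation flags bypass the convolution
block (replaced by a single 1x1 projection so downstream widths are
unchanged), the attention stage, or the positional encoding.

Everything is implemented directly on NumPy arrays — forward passes,
hand-derived backward passes, and an Adam optimizer — with all randomness
drawn from a single seeded generator, so training runs are exactly
reproducible.  Gradients are verified against finite differences in the
test suite.

The public surface follows the model/results convention: ``CrisprMCA`` is
constructed from data, ``fit()`` returns a :class:`CrisprMCAResults`
carrying the fitted parameters, the training history and prediction /
summary methods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError
from .encodings import encode_dataset
from .pairs import GuideTargetPair


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``branch_filters`` is the per-branch channel count of the convolution
    block; the attention width is the concatenation of the four branches,
    d_model = 4 * branch_filters.  ``use_multicnn`` / ``use_mha`` /
    ``use_posenc`` are the ablation toggles (M1 / M2 / M3).
    """

    input_len: int = 24
    input_channels: int = 7
    branch_filters: int = 32
    n_heads: int = 8
    dense_sizes: tuple[int, ...] = (256, 128, 2)
    dropout: float = 0.5
    use_multicnn: bool = True
    use_mha: bool = True
    use_posenc: bool = True
    max_epochs: int = 500
    patience: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 128
    monitor: str = "val_loss"
    seed: int = 0
    dtype: str = "float32"

    @property
    def d_model(self) -> int:
        return 4 * self.branch_filters

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0,1), got {self.dropout}")
        if not self.dense_sizes or self.dense_sizes[-1] != 2:
            raise ConfigurationError("dense head must end in a 2-unit output layer")
        if self.max_epochs < 1 or self.patience < 1:
            raise ConfigurationError("max_epochs and patience must be >= 1")
        if self.monitor not in ("val_loss", "train_loss"):
            raise ConfigurationError(f"unknown monitor {self.monitor!r}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigurationError(f"dtype must be float32 or float64, got {self.dtype!r}")


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding matrix of shape (L, d_model).

    Even columns carry sin(pos / 10000^(2i/d_model)), odd columns the
    matching cosine; entries lie in [-1, 1].
    """
    if L < 1 or d_model < 2:
        raise ConfigurationError("positional encoding needs L >= 1 and d_model >= 2")
    pos = np.arange(L, dtype=float)[:, None]
    idx = np.arange(d_model, dtype=float)[None, :]
    angle = pos / np.power(10000.0, (2.0 * np.floor(idx / 2.0)) / d_model)
    pe = np.where(idx.astype(int) % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


# ---------------------------------------------------------------------------
# layers (forward + hand-derived backward)
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _Param(_glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = _Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class Conv1DSame:
    """1-D convolution along the sequence axis with same-padding (im2col)."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        self.pad = kernel // 2
        self.W = _Param(_glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out)))
        self.b = _Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (N, L, C, k) -> (N, L, k, C) -> (N, L, k*C)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, L, self.kernel * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L, _ = self._shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += cols2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy @ self.W.value.T).reshape(n, L, self.kernel, self.c_in)
        dxp = np.zeros((n, L + 2 * self.pad, self.c_in), dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, self.pad : self.pad + L, :]


class MaxPool1DSame:
    """Width-3, stride-1 max pooling with same-padding; no parameters."""

    kernel = 3

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        self._shape = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win.transpose(0, 1, 3, 2)  # (N, L, k, C)
        self._argmax = win.argmax(axis=2)  # (N, L, C)
        return win.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L, c = self._shape
        pad = self.kernel // 2
        dxp = np.zeros((n, L + 2 * pad, c), dtype=dy.dtype)
        for j in range(self.kernel):
            mask = self._argmax == j
            contrib = np.where(mask, dy, 0.0)
            dxp[:, j : j + L, :] += contrib
        return dxp[:, pad : pad + L, :]


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class LayerNorm:
    """Normalization over the channel axis with learnable gain/bias."""

    eps = 1e-5

    def __init__(self, dim: int):
        self.gamma = _Param(np.ones(dim))
        self.beta = _Param(np.zeros(dim))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy.shape[-1]
        self.gamma.grad += (dy * self._xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.value
        return self._inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=-1, keepdims=True)
        )


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class MultiHeadSelfAttention:
    """Standard scaled dot-product self-attention with H parallel heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ConfigurationError("d_model must be divisible by n_heads")
        self.d = d_model
        self.h = n_heads
        self.dh = d_model // n_heads
        self.Wq = Dense(d_model, d_model, rng)
        self.Wk = Dense(d_model, d_model, rng)
        self.Wv = Dense(d_model, d_model, rng)
        self.Wo = Dense(d_model, d_model, rng)

    def params(self):
        return [p for lin in (self.Wq, self.Wk, self.Wv, self.Wo) for p in lin.params()]

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        return x.reshape(n, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, L, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.Wq.forward(x))
        k = self._split(self.Wk.forward(x))
        v = self._split(self.Wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ v
        self._q, self._k, self._v, self._attn = q, k, v, attn
        return self.Wo.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dctx = self._split(self.Wo.backward(dy))
        dattn = dctx @ self._v.transpose(0, 1, 3, 2)
        dv = self._attn.transpose(0, 1, 3, 2) @ dctx
        a = self._attn
        dscores = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
        dscores /= math.sqrt(self.dh)
        dq = dscores @ self._k
        dk = dscores.transpose(0, 1, 3, 2) @ self._q
        dx = self.Wq.backward(self._merge(dq))
        dx += self.Wk.backward(self._merge(dk))
        dx += self.Wv.backward(self._merge(dv))
        return dx


class MultiCNNBlock:
    """Four-branch multi-scale convolution block; channels concatenate.

    Branches: 1x1 conv; 1x1 -> width-3 conv; 1x1 -> width-5 conv;
    width-3 max-pool -> 1x1 conv.  ReLU after every convolution; spatial
    size preserved by same-padding, output channels = 4 * branch filters.
    """

    def __init__(self, c_in: int, filters: int, rng: np.random.Generator):
        self.filters = filters
        self.b1 = [Conv1DSame(1, c_in, filters, rng), ReLU()]
        self.b2 = [Conv1DSame(1, c_in, filters, rng), ReLU(),
                   Conv1DSame(3, filters, filters, rng), ReLU()]
        self.b3 = [Conv1DSame(1, c_in, filters, rng), ReLU(),
                   Conv1DSame(5, filters, filters, rng), ReLU()]
        self.b4 = [MaxPool1DSame(), Conv1DSame(1, c_in, filters, rng), ReLU()]
        self.branches = [self.b1, self.b2, self.b3, self.b4]

    def params(self):
        return [p for br in self.branches for layer in br for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = []
        for br in self.branches:
            h = x
            for layer in br:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.filters
        dx = None
        for i, br in enumerate(self.branches):
            d = dy[..., i * f : (i + 1) * f]
            for layer in reversed(br):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[_Param], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class CrisprMCA:
    """The off-target classifier, constructed from encoded training data.

    Parameters
    ----------
    X : ndarray, shape (N, input_len, input_channels)
        Encoded guide/target pairs (see :mod:`crisprmca.encodings`).
    y : ndarray of {0, 1}
        Activity labels.
    config : ModelConfig, optional
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.config.validate()
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        cfg = self.config
        if X.ndim != 3 or X.shape[1:] != (cfg.input_len, cfg.input_channels):
            raise ConfigurationError(
                f"X must be (N, {cfg.input_len}, {cfg.input_channels}), got {X.shape}"
            )
        if len(X) != len(y):
            raise ConfigurationError("X and y lengths differ")
        self._build()
        self.X, self.y = X.astype(self._dtype), y

    @classmethod
    def from_pairs(
        cls,
        pairs: list[GuideTargetPair],
        config: ModelConfig | None = None,
        scheme: str = "C3_24x7",
    ) -> "CrisprMCA":
        X = encode_dataset(pairs, scheme)
        y = np.array([p.label for p in pairs], dtype=int)
        return cls(X, y, config)

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        self._dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        if cfg.use_multicnn:
            self.cnn = MultiCNNBlock(cfg.input_channels, cfg.branch_filters, rng)
            self.proj = None
        else:
            self.cnn = None
            self.proj = [Conv1DSame(1, cfg.input_channels, d, rng), ReLU()]
        self.norm = LayerNorm(d)
        self.pe = positional_encoding(cfg.input_len, d) if cfg.use_posenc else None
        self.mha = MultiHeadSelfAttention(d, cfg.n_heads, rng) if cfg.use_mha else None
        flat = cfg.input_len * d
        sizes = (flat,) + tuple(cfg.dense_sizes)
        self.dense: list[Dense] = []
        self.dense_act: list[ReLU] = []
        self.dense_drop: list[Dropout] = []
        for i in range(len(cfg.dense_sizes)):
            self.dense.append(Dense(sizes[i], sizes[i + 1], rng))
            if i < len(cfg.dense_sizes) - 1:
                self.dense_act.append(ReLU())
                self.dense_drop.append(Dropout(cfg.dropout))
        if self.pe is not None:
            self.pe = self.pe.astype(self._dtype)
        for p in self.params():
            p.value = p.value.astype(self._dtype)
            p.grad = np.zeros_like(p.value)

    def params(self) -> list[_Param]:
        out: list[_Param] = []
        if self.cnn is not None:
            out += self.cnn.params()
        if self.proj is not None:
            out += [p for layer in self.proj for p in layer.params()]
        out += self.norm.params()
        if self.mha is not None:
            out += self.mha.params()
        for lin in self.dense:
            out += lin.params()
        return out

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    # -- forward / backward -------------------------------------------------

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Class probabilities, shape (N, 2); rows sum to 1."""
        h = np.asarray(X, dtype=self._dtype)
        if self.cnn is not None:
            h = self.cnn.forward(h)
        else:
            for layer in self.proj:
                h = layer.forward(h)
        h = self.norm.forward(h)
        if self.pe is not None:
            h = h + self.pe
        if self.mha is not None:
            h = h + self.mha.forward(h)
        n = h.shape[0]
        self._flat_shape = h.shape
        h = h.reshape(n, -1)
        for i, lin in enumerate(self.dense):
            h = lin.forward(h)
            if i < len(self.dense) - 1:
                h = self.dense_act[i].forward(h)
                h = self.dense_drop[i].forward(h, train, rng)
        logits = h - h.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def _backward_from_logits(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for i in range(len(self.dense) - 1, -1, -1):
            if i < len(self.dense) - 1:
                d = self.dense_drop[i].backward(d)
                d = self.dense_act[i].backward(d)
            d = self.dense[i].backward(d)
        d = d.reshape(self._flat_shape)
        if self.mha is not None:
            d = d + self.mha.backward(d)
        d = self.norm.backward(d)
        if self.cnn is not None:
            self.cnn.backward(d)
        else:
            for layer in reversed(self.proj):
                d = layer.backward(d)

    def loss_and_backward(
        self, X: np.ndarray, y: np.ndarray, train: bool, rng: np.random.Generator | None
    ) -> float:
        probs = self.forward(X, train=train, rng=rng)
        n = len(y)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(n), y].astype(np.float64) + eps)))
        if train:
            dlogits = probs.copy()
            dlogits[np.arange(n), y] -= 1.0
            dlogits /= n
            self._backward_from_logits(dlogits)
        return loss

    def evaluate_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(X, train=False)
        eps = 1e-12
        return -float(np.mean(np.log(probs[np.arange(len(y)), y].astype(np.float64) + eps)))

    # -- training ------------------------------------------------------------

    def fit(
        self,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        monitor_fn=None,
        verbose: bool = False,
    ) -> "CrisprMCAResults":
        """Train with Adam, early stopping, and best-weight restoration.

        Stops after ``max_epochs`` or once the monitored metric fails to
        improve for ``patience`` consecutive epochs.  ``monitor_fn`` (an
        optional callable receiving the history dict and returning the
        value to monitor) overrides the configured monitor; it exists for
        instrumentation and custom stopping criteria.
        """
        cfg = self.config
        if len(self.X) == 0:
            raise ConfigurationError("cannot fit on an empty training set")
        has_val = X_val is not None and y_val is not None
        if cfg.monitor == "val_loss" and not has_val and monitor_fn is None:
            monitor_key = "train_loss"
        else:
            monitor_key = cfg.monitor
        rng = np.random.default_rng(cfg.seed + 1)
        opt = _Adam(self.params(), cfg.learning_rate)
        history: dict[str, list[float]] = {"epoch": [], "train_loss": [], "val_loss": []}
        best = np.inf
        best_weights = self.get_weights()
        best_epoch = 0
        bad = 0
        n = len(self.X)
        stopped_epoch = cfg.max_epochs
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                losses.append(
                    self.loss_and_backward(self.X[idx], self.y[idx], train=True, rng=rng)
                )
                opt.step()
            train_loss = float(np.mean(losses))
            val_loss = self.evaluate_loss(X_val, y_val) if has_val else float("nan")
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if monitor_fn is not None:
                monitored = float(monitor_fn(history))
            else:
                monitored = val_loss if monitor_key == "val_loss" else train_loss
            if verbose:
                print(f"epoch {epoch}: train_loss={train_loss:.4f} val_loss={val_loss:.4f}")
            if monitored < best:
                best = monitored
                best_weights = self.get_weights()
                best_epoch = epoch
                bad = 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    stopped_epoch = epoch
                    break
        else:
            stopped_epoch = cfg.max_epochs
        self.set_weights(best_weights)
        return CrisprMCAResults(
            model=self,
            history=history,
            stopped_epoch=stopped_epoch,
            best_epoch=best_epoch,
            monitored_best=best,
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)


@dataclass
class CrisprMCAResults:
    """Fitted-model results: history, diagnostics, prediction, summary."""

    model: CrisprMCA
    history: dict[str, list[float]]
    stopped_epoch: int
    best_epoch: int
    monitored_best: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-record (P(inactive), P(active)) pairs."""
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "CRISPR-MCA fit results",
            "======================",
            f"parameters:        {self.model.n_params}",
            f"d_model / heads:   {cfg.d_model} / {cfg.n_heads}",
            f"ablations:         multicnn={cfg.use_multicnn} mha={cfg.use_mha} "
            f"posenc={cfg.use_posenc}",
            f"epochs run:        {self.stopped_epoch} (cap {cfg.max_epochs}, "
            f"patience {cfg.patience})",
            f"best epoch:        {self.best_epoch} "
            f"(monitored {cfg.monitor} = {self.monitored_best:.6f})",
            f"final train loss:  {self.history['train_loss'][-1]:.6f}",
        ]
        if not math.isnan(self.history["val_loss"][-1]):
            lines.append(f"final val loss:    {self.history['val_loss'][-1]:.6f}")
        return "\n".join(lines)


def train(
    model: CrisprMCA,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    **kwargs,
) -> CrisprMCAResults:
    """Functional alias for ``model.fit``."""
    return model.fit(X_val=X_val, y_val=y_val, **kwargs)
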