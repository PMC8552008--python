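"""Minimal NumPy neural-network primitives with manual backpropagation.

Implements exactly what the two autoencoders need: dense layers (optionally
applied time-distributed over sequences), ReLU, batch normalization,
unidirectional/bidirectional LSTM layers with full backpropagation through
time, and the Adam optimizer.  Everything is float64 and seeded, so training
runs are bitwise reproducible; gradients are validated against central
finite differences in the test suite.

Conventions: arrays are batch-first — ``(B, D)`` for poses, ``(B, T, D)``
for sequences.  Each layer caches what its ``backward`` needs during
``forward`` and accumulates parameter gradients into ``.grads``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid


class Layer:
    """Base class: parameter/gradient bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, (n_in, n_out))


def orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Stack of ``cols // n`` independent n x n orthogonal blocks."""
    blocks = []
    for _ in range(cols // n):
        q, r = np.linalg.qr(rng.normal(size=(n, n)))
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class Dense(Layer):
    """Affine map on the last axis; time-distributed over any leading axes."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        self._x2 = x.reshape(-1, self.n_in)
        y = self._x2 @ self.params["W"] + self.params["b"]
        return y.reshape(*self._shape[:-1], self.n_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.n_out)
        self.grads["W"] += self._x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return (dy2 @ self.params["W"].T).reshape(self._shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n), "beta": np.zeros(n)}
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean) / self._std
            return self.params["gamma"] * self._xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        xhat, std = self._xhat, self._std
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class LSTM(Layer):
    """Single-direction LSTM over (B, T, D) returning the full (B, T, H)
    hidden sequence.  ``reverse=True`` consumes the sequence back-to-front
    (outputs stay aligned with input time, so out[:, t] has then seen
    x[:, t:]).  Gate order: input, forget, cell, output; forget bias 1."""

    def __init__(
        self,
        n_in: int,
        hidden: int,
        rng: np.random.Generator,
        reverse: bool = False,
    ) -> None:
        super().__init__()
        self.n_in, self.hidden, self.reverse = n_in, hidden, reverse
        h = hidden
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params = {
            "W": glorot(rng, n_in, 4 * h),
            "U": orthogonal(rng, h, 4 * h),
            "b": b,
        }
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.reverse:
            x = x[:, ::-1]
        B, T, _ = x.shape
        h = self.hidden
        xw = x.reshape(-1, self.n_in) @ self.params["W"] + self.params["b"]
        xw = xw.reshape(B, T, 4 * h)
        U = self.params["U"]
        i = np.empty((B, T, h)); f = np.empty((B, T, h))
        g = np.empty((B, T, h)); o = np.empty((B, T, h))
        c = np.empty((B, T, h)); tc = np.empty((B, T, h))
        hs = np.empty((B, T, h))
        h_prev = np.zeros((B, h))
        c_prev = np.zeros((B, h))
        for t in range(T):
            z = xw[:, t] + h_prev @ U
            i[:, t] = _sigmoid(z[:, :h])
            f[:, t] = _sigmoid(z[:, h : 2 * h])
            g[:, t] = np.tanh(z[:, 2 * h : 3 * h])
            o[:, t] = _sigmoid(z[:, 3 * h :])
            c[:, t] = f[:, t] * c_prev + i[:, t] * g[:, t]
            tc[:, t] = np.tanh(c[:, t])
            hs[:, t] = o[:, t] * tc[:, t]
            h_prev, c_prev = hs[:, t], c[:, t]
        self._cache = (x, i, f, g, o, c, tc, hs)
        return hs[:, ::-1] if self.reverse else hs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.reverse:
            dy = dy[:, ::-1]
        x, i, f, g, o, c, tc, hs = self._cache
        B, T, _ = x.shape
        h = self.hidden
        U = self.params["U"]
        dxw = np.empty((B, T, 4 * h))
        dU = np.zeros_like(U)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            dh = dy[:, t] + dh_next
            c_prev = c[:, t - 1] if t > 0 else np.zeros((B, h))
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, h))
            do = dh * tc[:, t]
            dct = dh * o[:, t] * (1 - tc[:, t] ** 2) + dc_next
            di = dct * g[:, t]
            df = dct * c_prev
            dg = dct * i[:, t]
            dz = np.concatenate(
                [
                    di * i[:, t] * (1 - i[:, t]),
                    df * f[:, t] * (1 - f[:, t]),
                    dg * (1 - g[:, t] ** 2),
                    do * o[:, t] * (1 - o[:, t]),
                ],
                axis=1,
            )
            dxw[:, t] = dz
            dU += h_prev.T @ dz
            dh_next = dz @ U.T
            dc_next = dct * f[:, t]
        dxw2 = dxw.reshape(-1, 4 * h)
        self.grads["W"] += x.reshape(-1, self.n_in).T @ dxw2
        self.grads["U"] += dU
        self.grads["b"] += dxw2.sum(axis=0)
        dx = (dxw2 @ self.params["W"].T).reshape(B, T, self.n_in)
        return dx[:, ::-1] if self.reverse else dx


class BiLSTM(Layer):
    """Concatenation of a forward and a backward LSTM: (B,T,D) -> (B,T,2H).

    The "final state" of the layer is ``out[:, -1, :H]`` (forward direction
    after the whole sequence) concatenated with ``out[:, 0, H:]`` (backward
    direction after the whole sequence).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        self.fwd = LSTM(n_in, hidden, rng, reverse=False)
        self.bwd = LSTM(n_in, hidden, rng, reverse=True)

    @property
    def children(self) -> list[Layer]:
        return [self.fwd, self.bwd]

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=2
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.hidden
        return self.fwd.backward(dy[:, :, :h]) + self.bwd.backward(dy[:, :, h:])

    def final_state(self, out: np.ndarray) -> np.ndarray:
        h = self.hidden
        return np.concatenate([out[:, -1, :h], out[:, 0, h:]], axis=1)

    def final_state_grad(self, d_final: np.ndarray, shape) -> np.ndarray:
        h = self.hidden
        dy = np.zeros(shape)
        dy[:, -1, :h] = d_final[:, :h]
        dy[:, 0, h:] = d_final[:, h:]
        return dy


def iter_layers(layers) -> list[Layer]:
    """Flatten BiLSTM wrappers into their directional children."""
    flat: list[Layer] = []
    for layer in layers:
        if isinstance(layer, BiLSTM):
            flat.extend(layer.children)
        else:
            flat.append(layer)
    return flat


class Adam:
    """Adaptive moment estimation over the parameters of a set of layers."""

    def __init__(
        self,
        layers,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = iter_layers(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.beta1**self.t
        bc2 = 1 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                grad = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * grad
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * grad**2
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def zero_all(layers) -> None:
    for layer in iter_layers(layers):
        layer.zero_grads()


def clip_gradients(layers, max_norm: float) -> None:
    flat = iter_layers(layers)
    total = np.sqrt(
        sum(float(np.sum(g**2)) for l in flat for g in l.grads.values())
    )
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for l in flat:
            for k in l.grads:
                l.grads[k] *= scale


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the iteration at which it happened."""

    def __init__(self, iteration: int) -> None:
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


def collect_params(layers) -> dict[str, np.ndarray]:
    out = {}
    for idx, layer in enumerate(iter_layers(layers)):
        for k, v in layer.params.items():
            out[f"layer{idx}_{k}"] = v
        if isinstance(layer, BatchNorm):
            out[f"layer{idx}_running_mean"] = layer.running_mean
            out[f"layer{idx}_running_var"] = layer.running_var
    return out


def restore_params(layers, blob: dict[str, np.ndarray]) -> None:
    for idx, layer in enumerate(iter_layers(layers)):
        for k in layer.params:
            layer.params[k] = np.array(blob[f"layer{idx}_{k}"])
        if isinstance(layer, BatchNorm):
            layer.running_mean = np.array(blob[f"layer{idx}_running_mean"])
            layer.running_var = np.array(blob[f"layer{idx}_running_var"])
        layer.zero_grads()
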