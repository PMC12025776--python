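"""Minimal numpy neural-network engine used by the PPG quality classifiers.

Layers implement ``forward(x, train)`` / ``backward(dout)`` with explicit
gradient formulas; trainable tensors live in ``layer.params`` and their
gradients in ``layer.grads`` after a backward pass.  Non-trainable state
(batch-norm running statistics) lives in ``layer.buffers``.

Shape conventions:

* channel-major sequences ``(N, C, L)`` for conv / pooling / batch-norm,
* time-major sequences ``(N, L, F)`` for recurrent layers,
* flat features ``(N, F)`` for dense and KAN layers.

The engine is deliberately small: exactly the pieces the three
architectures need, each verified against finite-difference gradients in
the test suite.
"""

from __future__ import annotations

import numpy as np

from .kan import SplineSpec, bspline_design_matrix

__all__ = [
    "Layer", "Dense", "Activation", "Conv1d", "BatchNorm1d", "MaxPool1d",
    "AddChannel", "ChannelMean", "ToTimeMajor", "BiLSTM", "GlobalAvgPool", "KanDense",
    "Network", "Adam", "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Dense(Layer):
    """Affine map (N, D) -> (N, M)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))  # Glorot uniform
        self.params["W"] = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Activation(Layer):
    """Fixed elementwise nonlinearity: relu, sigmoid or tanh."""

    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train=False):
        if self.kind == "relu":
            self._out = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            self._out = sigmoid(x)
        else:
            self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        if self.kind == "relu":
            return dout * (self._out > 0)
        if self.kind == "sigmoid":
            return dout * self._out * (1.0 - self._out)
        return dout * (1.0 - self._out**2)


class Conv1d(Layer):
    """1D valid cross-correlation (N, C_in, L) -> (N, C_out, L_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1) -> None:
        super().__init__()
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        self.kernel_size = kernel_size
        self.stride = stride
        bound = np.sqrt(1.0 / (in_channels * kernel_size))
        self.params["W"] = rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size))
        self.params["b"] = np.zeros(out_channels)

    def out_length(self, length: int) -> int:
        if length < self.kernel_size:
            raise ValueError(f"input length {length} shorter than kernel {self.kernel_size}")
        return (length - self.kernel_size) // self.stride + 1

    def forward(self, x, train=False):
        n, c, length = x.shape
        l_out = self.out_length(length)
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=2)
        windows = windows[:, :, :: self.stride][:, :, :l_out]
        self._windows, self._in_shape = windows, x.shape
        out = np.einsum("nclk,ock->nol", windows, self.params["W"], optimize=True)
        return out + self.params["b"][:, None]

    def backward(self, dout):
        self.grads["W"] = np.einsum("nclk,nol->ock", self._windows, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        n, c, length = self._in_shape
        dx = np.zeros(self._in_shape)
        l_out = dout.shape[2]
        for k in range(self.kernel_size):
            contrib = np.einsum("nol,oc->ncl", dout, self.params["W"][:, :, k], optimize=True)
            dx[:, :, k : k + self.stride * l_out : self.stride] += contrib
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization for (N, C, L) tensors."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.buffers["running_mean"] = (
                (1 - self.momentum) * self.buffers["running_mean"] + self.momentum * mean
            )
            self.buffers["running_var"] = (
                (1 - self.momentum) * self.buffers["running_var"] + self.momentum * var
            )
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._inv_std[:, None]
        self._m = x.shape[0] * x.shape[2]
        self._train = train
        return self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]

    def backward(self, dout):
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][:, None]
        if not self._train:
            return dxhat * self._inv_std[:, None]
        m = self._m
        term = (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        return self._inv_std[:, None] / m * term


class MaxPool1d(Layer):
    """Non-overlapping temporal max pooling (N, C, L) -> (N, C, L // pool)."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x, train=False):
        n, c, length = x.shape
        l_out = length // self.pool
        trimmed = x[:, :, : l_out * self.pool].reshape(n, c, l_out, self.pool)
        self._argmax = trimmed.argmax(axis=3)
        self._in_shape = x.shape
        return trimmed.max(axis=3)

    def backward(self, dout):
        n, c, l_out = dout.shape
        dtrim = np.zeros((n, c, l_out, self.pool))
        np.put_along_axis(dtrim, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : l_out * self.pool] = dtrim.reshape(n, c, l_out * self.pool)
        return dx


class AddChannel(Layer):
    """Insert a singleton channel axis: (N, L) -> (N, 1, L)."""

    def forward(self, x, train=False):
        return x[:, None, :]

    def backward(self, dout):
        return dout[:, 0, :]


class ChannelMean(Layer):
    """Average across channels: (N, C, L) -> (N, L)."""

    def forward(self, x, train=False):
        self._c = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._c, axis=1) / self._c


class ToTimeMajor(Layer):
    """Reorder (N, C, L) -> (N, L, C) for recurrent layers."""

    def forward(self, x, train=False):
        return x.transpose(0, 2, 1)

    def backward(self, dout):
        return dout.transpose(0, 2, 1)


class GlobalAvgPool(Layer):
    """Mean over the time axis: (N, L, F) -> (N, F)."""

    def forward(self, x, train=False):
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._l, axis=1) / self._l


class _LSTMDirection:
    """One direction of an LSTM; gates ordered (input, forget, cell, output)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-bound, bound, size=(in_dim, 4 * hidden))
        self.Wh = rng.uniform(-bound, bound, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        # forget-gate bias of 1 stabilises early training
        self.b[hidden : 2 * hidden] = 1.0
        self.hidden = hidden

    def forward(self, x):
        n, length, _ = x.shape
        h_dim = self.hidden
        pre = x @ self.Wx + self.b
        i = np.empty((n, length, h_dim)); f = np.empty_like(i)
        g = np.empty_like(i); o = np.empty_like(i)
        c = np.empty_like(i); h = np.empty_like(i)
        h_t = np.zeros((n, h_dim)); c_t = np.zeros((n, h_dim))
        for t in range(length):
            a = pre[:, t] + h_t @ self.Wh
            i[:, t] = sigmoid(a[:, :h_dim])
            f[:, t] = sigmoid(a[:, h_dim : 2 * h_dim])
            g[:, t] = np.tanh(a[:, 2 * h_dim : 3 * h_dim])
            o[:, t] = sigmoid(a[:, 3 * h_dim :])
            c_t = f[:, t] * c_t + i[:, t] * g[:, t]
            h_t = o[:, t] * np.tanh(c_t)
            c[:, t] = c_t
            h[:, t] = h_t
        self._cache = (x, i, f, g, o, c, h)
        return h

    def backward(self, dout):
        x, i, f, g, o, c, h = self._cache
        n, length, h_dim = dout.shape
        dpre = np.empty((n, length, 4 * h_dim))
        dWh = np.zeros_like(self.Wh)
        dh_next = np.zeros((n, h_dim)); dc_next = np.zeros((n, h_dim))
        for t in range(length - 1, -1, -1):
            dh = dout[:, t] + dh_next
            tc = np.tanh(c[:, t])
            do = dh * tc
            dc = dc_next + dh * o[:, t] * (1.0 - tc**2)
            c_prev = c[:, t - 1] if t > 0 else np.zeros((n, h_dim))
            di = dc * g[:, t]
            df = dc * c_prev
            dg = dc * i[:, t]
            dc_next = dc * f[:, t]
            da = np.concatenate([
                di * i[:, t] * (1 - i[:, t]),
                df * f[:, t] * (1 - f[:, t]),
                dg * (1 - g[:, t] ** 2),
                do * o[:, t] * (1 - o[:, t]),
            ], axis=1)
            dpre[:, t] = da
            h_prev = h[:, t - 1] if t > 0 else np.zeros((n, h_dim))
            dWh += h_prev.T @ da
            dh_next = da @ self.Wh.T
        flat_x = x.reshape(n * length, -1)
        flat_dpre = dpre.reshape(n * length, -1)
        dWx = flat_x.T @ flat_dpre
        db = flat_dpre.sum(axis=0)
        dx = (flat_dpre @ self.Wx.T).reshape(x.shape)
        return dx, dWx, dWh, db


class BiLSTM(Layer):
    """(Bi)directional LSTM over (N, L, D); output (N, L, H * dirs).

    Uses a single bias vector per direction (the two torch bias vectors are
    redundant at inference and would only double-count parameters).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 bidirectional: bool = True) -> None:
        super().__init__()
        self.hidden = hidden
        self.bidirectional = bidirectional
        self._dirs = [_LSTMDirection(in_dim, hidden, rng)]
        if bidirectional:
            self._dirs.append(_LSTMDirection(in_dim, hidden, rng))
        for d, direction in enumerate(self._dirs):
            self.params[f"Wx{d}"] = direction.Wx
            self.params[f"Wh{d}"] = direction.Wh
            self.params[f"b{d}"] = direction.b

    def forward(self, x, train=False):
        outs = [self._dirs[0].forward(x)]
        if self.bidirectional:
            outs.append(self._dirs[1].forward(x[:, ::-1])[:, ::-1])
        return np.concatenate(outs, axis=2)

    def backward(self, dout):
        h_dim = self.hidden
        dx, dWx, dWh, db = self._dirs[0].backward(dout[:, :, :h_dim])
        self.grads["Wx0"], self.grads["Wh0"], self.grads["b0"] = dWx, dWh, db
        if self.bidirectional:
            dx2, dWx2, dWh2, db2 = self._dirs[1].backward(dout[:, ::-1, h_dim:])
            self.grads["Wx1"], self.grads["Wh1"], self.grads["b1"] = dWx2, dWh2, db2
            dx = dx + dx2[:, ::-1]
        return dx


class KanDense(Layer):
    """Trainable Kolmogorov-Arnold layer on flat features (N, D) -> (N, M).

    Every input-output edge carries its own spline function; the layer
    output is the per-output sum of edge activations, with no fixed
    nonlinearity.  Inputs outside the spline domain are clamped to the
    boundary (their input-gradient is zero there).
    """

    def __init__(self, in_dim: int, out_dim: int, spec: SplineSpec,
                 rng: np.random.Generator, init_scale: float = 0.1) -> None:
        super().__init__()
        self.in_dim, self.out_dim, self.spec = in_dim, out_dim, spec
        self.params["coeffs"] = rng.normal(0.0, init_scale, size=(out_dim, in_dim, spec.n_basis))

    def forward(self, x, train=False):
        lo, hi = self.spec.domain_lo, self.spec.domain_hi
        self._interior = (x > lo) & (x < hi)
        xc = np.clip(x, lo, hi)
        self._basis = bspline_design_matrix(xc, self.spec, warn=False)
        self._xc = xc
        return np.einsum("nim,oim->no", self._basis, self.params["coeffs"], optimize=True)

    def backward(self, dout):
        self.grads["coeffs"] = np.einsum("no,nim->oim", dout, self._basis, optimize=True)
        dbasis = bspline_design_matrix(self._xc, self.spec, derivative=True, warn=False)
        dx = np.einsum("no,oim,nim->ni", dout, self.params["coeffs"], dbasis, optimize=True)
        return dx * self._interior


class Network:
    """A plain sequential stack of layers with shared train/eval semantics."""

    def __init__(self, layers: list[Layer], name: str = "network") -> None:
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities in (0, 1) for a batch of signals.

        Clipped away from the interval ends so saturated logits still give
        strictly interior probabilities.
        """
        logits = self.forward(x, train=False)
        p = sigmoid(logits[:, -1] if logits.ndim == 2 else logits)
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def parameters(self):
        for idx, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{idx}.{name}", layer, name, value

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.layers)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: value.copy() for key, _, _, value in self.parameters()}
        for idx, layer in enumerate(self.layers):
            for name, value in layer.buffers.items():
                state[f"{idx}.buffer.{name}"] = value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, value in self.parameters():
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in state dict")
            if state[key].shape != value.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            layer.params[name] = state[key].copy()
        for idx, layer in enumerate(self.layers):
            for name in layer.buffers:
                key = f"{idx}.buffer.{name}"
                if key in state:
                    layer.buffers[name] = state[key].copy()
        # _LSTMDirection keeps direct references; re-bind after loading
        for layer in self.layers:
            if isinstance(layer, BiLSTM):
                for d, direction in enumerate(layer._dirs):
                    direction.Wx = layer.params[f"Wx{d}"]
                    direction.Wh = layer.params[f"Wh{d}"]
                    direction.b = layer.params[f"b{d}"]


class Adam:
    """Adam optimizer over all trainable tensors of a network."""

    def __init__(self, network: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {key: np.zeros_like(v) for key, _, _, v in network.parameters()}
        self._v = {key: np.zeros_like(v) for key, _, _, v in network.parameters()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for key, layer, name, value in self.network.parameters():
            grad = layer.grads.get(name)
            if grad is None:
                continue
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * grad
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * grad**2
            value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
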