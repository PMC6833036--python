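"""Minimal 1-D neural-network primitives on numpy.

Every layer implements ``forward`` / ``backward`` explicitly so that the
whole training loop is deterministic given seeded generators, parameters
can be frozen tensor-by-tensor, and no external deep-learning framework
is required.  Array layout is ``[batch, width, channels]`` throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def same_padding(w_in: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output width and (left, right) zero padding for 'same' coverage.

    Output width is ``ceil(w_in / stride)`` so that stride-2 layers halve
    even widths exactly.
    """
    w_out = -(-w_in // stride)
    pad = max((w_out - 1) * stride + kernel - w_in, 0)
    left = pad // 2
    return w_out, left, pad - left


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding.

    Weights have shape ``[kernel, in_channels, out_channels]``; fan-in for
    initialisation purposes is ``kernel * in_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 16,
                 stride: int = 1):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.W = np.zeros((kernel, in_channels, out_channels), DTYPE)
        self.b = np.zeros(out_channels, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def fan_in(self) -> int:
        return self.kernel * self.in_channels

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        m, w_in, c = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k, s = self.kernel, self.stride
        w_out, pl, pr = same_padding(w_in, k, s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # two algebraically identical kernels; the faster one depends on
        # the channel count (measured on 1-CPU numpy)
        if c == 1:
            win = sliding_window_view(xp, k, axis=1)[:, ::s]
            y = np.einsum("mwck,kco->mwo", win, self.W, optimize=True)
            y += self.b
        else:
            y = np.tile(self.b, (m, w_out, 1)).astype(DTYPE)
            for j in range(k):
                y += xp[:, j:j + s * w_out:s, :] @ self.W[j]
        self._cache = (xp, w_in, w_out, pl)
        return y.astype(DTYPE, copy=False)

    def backward(self, dout):
        xp, w_in, w_out, pl = self._cache
        m = dout.shape[0]
        k, s = self.kernel, self.stride
        cin, cout = self.in_channels, self.out_channels
        # weight gradient, tap by tap
        dr = dout.reshape(m * w_out, cout)
        for j in range(k):
            xk = xp[:, j:j + s * w_out:s, :].reshape(m * w_out, cin)
            self.dW[j] = xk.T @ dr
        self.db[...] = dout.sum(axis=(0, 1))
        # input gradient as a full correlation of the zero-dilated output
        # gradient with the tap-reversed, channel-transposed kernel
        g = np.zeros((m, (w_out - 1) * s + 1, cout), dout.dtype)
        g[:, ::s] = dout
        gp = np.pad(g, ((0, 0), (k - 1, k - 1), (0, 0)))
        length = gp.shape[1] - k + 1    # == (w_out - 1) * stride + k
        if s == 1 and cin >= 8:
            gwin = np.ascontiguousarray(sliding_window_view(gp, k, axis=1))
            # rows indexed (out_channel, tap): wf[(o, j), c] = W[k-1-j, c, o]
            wf = self.W[::-1].transpose(2, 0, 1).reshape(cout * k, cin)
            dxp = (gwin.reshape(m * length, cout * k) @ wf
                   ).reshape(m, length, cin)
        else:
            dxp = np.zeros((m, length, cin), dout.dtype)
            for j in range(k):
                dxp += gp[:, j:j + length, :] @ self.W[k - 1 - j].T
        return dxp[:, pl:pl + w_in].astype(DTYPE, copy=False)


class MaxPool1D(Layer):
    """Max pooling with 'same' padding (pad value -inf)."""

    def __init__(self, kernel: int = 16, stride: int = 2):
        self.kernel = kernel
        self.stride = stride
        self._cache = None

    def forward(self, x, training=False):
        m, w_in, c = x.shape
        w_out, pl, pr = same_padding(w_in, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, self.kernel, axis=1)[:, ::self.stride]
        idx = win.argmax(axis=-1)  # [m, w_out, c]
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, m, w_in, c, xp.shape[1], pl)
        return y.astype(DTYPE, copy=False)

    def backward(self, dout):
        idx, m, w_in, c, w_pad, pl = self._cache
        w_out = dout.shape[1]
        dxp = np.zeros((m, w_pad, c), dout.dtype)
        pos = np.arange(w_out)[None, :, None] * self.stride + idx
        flat = (np.arange(m)[:, None, None] * w_pad + pos) * c \
            + np.arange(c)[None, None, :]
        np.add.at(dxp.reshape(-1), flat.reshape(-1), dout.reshape(-1))
        return dxp[:, pl:pl + w_in].astype(DTYPE, copy=False)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, width).

    ``frozen=True`` forces inference behaviour (running statistics, no
    statistic updates) even when ``training=True`` — used for frozen
    stages during transfer training.
    """

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, DTYPE)
        self.beta = np.zeros(channels, DTYPE)
        self.running_mean = np.zeros(channels, DTYPE)
        self.running_var = np.ones(channels, DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.frozen = False
        self._cache = None
        self._collect: tuple[list, list] | None = None  # stat re-estimation

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def reset(self):
        self.gamma[...] = 1.0
        self.beta[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x, training=False):
        collecting = self._collect is not None and not self.frozen
        use_batch = (training or collecting) and not self.frozen
        if use_batch:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            if collecting:
                self._collect[0].append(mu)
                self._collect[1].append(var)
            else:
                self.running_mean[...] = (self.momentum * self.running_mean
                                          + (1.0 - self.momentum) * mu)
                self.running_var[...] = (self.momentum * self.running_var
                                         + (1.0 - self.momentum) * var)
        else:
            mu = self.running_mean
            var = self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, x - mu, use_batch, x.shape[0] * x.shape[1])
        return (self.gamma * xhat + self.beta).astype(DTYPE, copy=False)

    def backward(self, dout):
        xhat, ivar, xc, use_batch, n = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        if not use_batch:
            return (dxhat * ivar).astype(DTYPE, copy=False)
        dvar = (dxhat * xc).sum(axis=(0, 1)) * -0.5 * ivar ** 3
        dmu = (-(dxhat * ivar).sum(axis=(0, 1))
               + dvar * -2.0 * xc.mean(axis=(0, 1)))
        dx = dxhat * ivar + dvar * 2.0 * xc / n + dmu / n
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(DTYPE, copy=False)


class Dropout(Layer):
    """Inverted dropout; a generator must be supplied in training mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng: np.random.Generator | None = None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(DTYPE, copy=False)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(DTYPE, copy=False)


class Dense(Layer):
    """Affine map on flattened features: [m, n_in] -> [m, n_out]."""

    def __init__(self, n_in: int, n_out: int):
        self.n_in = n_in
        self.n_out = n_out
        self.W = np.zeros((n_in, n_out), DTYPE)
        self.b = np.zeros(n_out, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def fan_in(self) -> int:
        return self.n_in

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return (x @ self.W + self.b).astype(DTYPE, copy=False)

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return (dout @ self.W.T).astype(DTYPE, copy=False)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with bias correction; per-tensor state keyed by caller."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, named_params: list[tuple[str, np.ndarray, np.ndarray]],
             lr: float) -> None:
        """In-place update of each (key, param, grad) triple."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p, g in named_params:
            if key not in self.state:
                self.state[key] = (np.zeros_like(p, dtype=np.float64),
                                   np.zeros_like(p, dtype=np.float64))
            m, v = self.state[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g, dtype=np.float64)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
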