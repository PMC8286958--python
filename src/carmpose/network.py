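"""A compact CNN implemented in numpy with manual backpropagation.

The regression architecture is four strided convolutional blocks (batch
normalization after every convolution, ReLU after every second one)
followed by three fully connected layers.  Networks of this size train in
minutes on a single CPU core, which is all the desk-scale experiments need;
the implementation is deliberately minimal — exactly the layers the
architecture uses, an Adam optimizer, and nothing else.

All parameter initialization and batch sampling is driven by explicit
generators, so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "ConvNet", "Adam", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The block/layer structure is fixed (four conv blocks, three FC layers);
    widths are tunable.  ``channels`` are the conv output channels per
    block, ``fc`` the two hidden FC widths (the third FC layer is the
    output head).
    """

    input_size: int = 256
    channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    fc: tuple[int, int] = (1024, 256)
    kernel: int = 3
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.channels) != 4:
            raise ValueError("exactly four convolutional blocks are required")
        if len(self.fc) != 2:
            raise ValueError("exactly three fully connected layers are required (two hidden)")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 (four stride-2 blocks)")

    @property
    def conv_blocks(self) -> int:
        return 4

    @property
    def fc_layers(self) -> int:
        return 3


# ---------------------------------------------------------------------------
# layers


class Conv2d:
    """3x3 convolution with stride 2 and padding 1 (im2col based)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self.kernel = kernel
        self.pad = kernel // 2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p, k, s = self.pad, self.kernel, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._windows = windows
        self._x_shape = x.shape
        out = np.tensordot(windows, self.w, axes=([1, 4, 5], [1, 2, 3]))
        return out.transpose(0, 3, 1, 2) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p, k, s = self.pad, self.kernel, self.stride
        n, c_in, h, w = self._x_shape
        _, _, ho, wo = dout.shape
        self.gw[...] = np.tensordot(dout, self._windows, axes=([0, 2, 3], [0, 2, 3]))
        self.gb[...] = dout.sum(axis=(0, 2, 3))
        dxp = np.zeros((n, c_in, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                contrib = np.tensordot(dout, self.w[:, :, ki, kj], axes=([1], [0]))
                dxp[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += contrib.transpose(
                    0, 3, 1, 2
                )
        self._windows = None
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.ggamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = dout.sum(axis=(0, 2, 3))
        d_mean = dout.mean(axis=(0, 2, 3))
        d_xhat_mean = (dout * xhat).mean(axis=(0, 2, 3))
        dx = (
            self.gamma[None, :, None, None]
            * inv[None, :, None, None]
            * (dout - d_mean[None, :, None, None] - xhat * d_xhat_mean[None, :, None, None])
        )
        self._xhat = self._inv = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gw[...] = self._x.T @ dout
        self.gb[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


class ConvNet:
    """Sequential container over the layers above."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, value, grad in layer.params():
                out.append((f"{i}.{name}", value, grad))
        return out

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: value.copy() for name, value, _ in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.run_mean"] = layer.run_mean.copy()
                state[f"{i}.run_var"] = layer.run_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _ in self.parameters():
            value[...] = state[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.run_mean[...] = state[f"{i}.run_mean"]
                layer.run_var[...] = state[f"{i}.run_var"]


def build_model(config: ModelConfig, n_outputs: int, seed: int = 0) -> ConvNet:
    """Assemble the 4-conv-block / 3-FC regression network.

    ReLU follows every second convolution; batch normalization every
    convolution (when enabled).  Spatial size halves per block, so the
    flattened feature length is ``channels[-1] * (input_size / 16)**2``.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    c_prev = 1
    for i, c in enumerate(config.channels):
        layers.append(Conv2d(c_prev, c, config.kernel, stride=2, rng=rng))
        if config.batch_norm:
            layers.append(BatchNorm2d(c))
        if i % 2 == 1:
            layers.append(ReLU())
        c_prev = c
    feat = config.channels[-1] * (config.input_size // 16) ** 2
    layers.append(Flatten())
    layers.append(Linear(feat, config.fc[0], rng))
    layers.append(ReLU())
    layers.append(Linear(config.fc[0], config.fc[1], rng))
    layers.append(ReLU())
    layers.append(Linear(config.fc[1], n_outputs, rng))
    return ConvNet(layers)


class Adam:
    """Adam optimizer over a ConvNet's parameters."""

    def __init__(self, net: ConvNet, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in net.parameters()}
        self.v = {name: np.zeros_like(v) for name, v, _ in net.parameters()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, value, grad in self.net.parameters():
            m = self.m[name]
            v = self.v[name]
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
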