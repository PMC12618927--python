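"""Neural-network building blocks on top of the autodiff engine.

Initialization follows Xavier (Glorot) normal throughout, drawn from an
explicit ``numpy.random.Generator`` so that identical seeds give identical
models on every platform.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, conv2d, conv_transpose2d, maxpool2x2

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MaxPool2x2",
    "Dropout",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Sequential",
    "xavier_normal",
]


def xavier_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Module:
    """Base class: parameter discovery, train/eval mode, state flattening."""

    def __init__(self):
        self.training = True

    def _public_values(self):
        # names starting with "_" are caches/scratch, never model state
        return [v for k, v in self.__dict__.items() if not k.startswith("_")]

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self._public_values():
            params.extend(_collect(v))
        return params

    def train(self):
        self.training = True
        for v in self._public_values():
            for m in _modules(v):
                m.train()
        return self

    def eval(self):
        self.training = False
        for v in self._public_values():
            for m in _modules(v):
                m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus non-trainable buffers, in a stable order."""
        arrs = [p.data for p in self.parameters()]
        arrs.extend(self.buffers())
        return arrs

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for v in self._public_values():
            for m in _modules(v):
                bufs.extend(m.buffers())
        return bufs

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        n = len(params)
        for p, a in zip(params, arrays[:n]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)
        self._load_buffers(list(arrays[n:]))

    def _load_buffers(self, bufs: list[np.ndarray]) -> None:
        for v in self._public_values():
            for m in _modules(v):
                m._load_buffers_own(bufs)

    def _load_buffers_own(self, bufs):
        self._load_buffers(bufs)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _modules(v):
    if isinstance(v, Module):
        return [v]
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_modules(item))
        return out
    return []


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Tensor(
            xavier_normal(rng, (in_features, out_features), in_features, out_features),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x):
        out = as_tensor(x) @ self.w
        return out + self.b if self.b is not None else out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.w = Tensor(
            xavier_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, fan_out),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 output_padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.w = Tensor(
            xavier_normal(rng, (in_ch, out_ch, kernel, kernel), fan_in, fan_out),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x):
        return conv_transpose2d(x, self.w, self.b, stride=self.stride,
                                padding=self.padding,
                                output_padding=self.output_padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics and updates exponential
    running estimates; eval mode uses the frozen running estimates, which is
    what makes codec inference deterministic.
    """

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)
        self.running_mean = np.zeros(num_ch)
        self.running_var = np.ones(num_ch)
        self.momentum, self.eps = momentum, eps

    def buffers(self):
        return [self.running_mean, self.running_var]

    def _load_buffers_own(self, bufs):
        self.running_mean = np.asarray(bufs.pop(0), dtype=np.float64)
        self.running_var = np.asarray(bufs.pop(0), dtype=np.float64)

    def forward(self, x):
        x = as_tensor(x)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class MaxPool2x2(Module):
    def forward(self, x):
        return maxpool2x2(x)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  The mask generator is owned
    by the layer so a reseeded model replays the same masks."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        x = as_tensor(x)
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return as_tensor(x).relu()


class Tanh(Module):
    def forward(self, x):
        return as_tensor(x).tanh()


class Sigmoid(Module):
    def forward(self, x):
        return as_tensor(x).sigmoid()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
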