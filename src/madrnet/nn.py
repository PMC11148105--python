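"""Neural-network layer primitives on top of :mod:`madrnet.autograd`.

Follows the familiar Module/Parameter pattern: a :class:`Module` owns
parameters and submodules, exposes ``parameters()`` / ``named_parameters()``
for optimizers and checkpointing, and a ``train()`` / ``eval()`` mode switch
(batch normalization is the only mode-dependent layer).

Weight initialization is explicit and reproducible: every layer draws its
initial weights from the ``rng`` (a ``numpy.random.Generator``) handed to its
constructor, so a model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module") -> None:
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield (prefix + name, p)
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (prefix + name, b)
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        # buffers are rebound on their owning module so attribute access stays live
        for module_prefix, module in self._iter_named_modules(""):
            for bname in list(module._buffers):
                key = "buffer:" + module_prefix + bname
                if key in state:
                    module.register_buffer(bname, np.asarray(state[key]))

    def _iter_named_modules(self, prefix: str):
        yield prefix, self
        for mname, m in self._modules.items():
            yield from m._iter_named_modules(prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self.add_module(str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Conv2d(Module):
    """Dilated 2-D convolution with "same" zero padding and odd kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = int(dilation)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """2x2, stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, in_channels: int, out_channels: int, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes with batch statistics and tracks exponential
    running moments (momentum 0.1); eval mode uses the running moments.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu.data.ravel()).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var.data.ravel()).astype(DTYPE)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        w = ag.reshape(self.weight, (1, -1, 1, 1))
        b = ag.reshape(self.bias, (1, -1, 1, 1))
        return xhat * w + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    e = ag.exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)
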