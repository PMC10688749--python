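"""Layer modules: parameter containers over the functional ops.

A `Module` owns named parameters and submodules, exposes a flat
``state_dict`` of NumPy arrays for checkpointing, and a ``train``/``eval``
switch that only batch normalisation cares about.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

DTYPE = np.float32


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    # registration happens implicitly through attribute assignment
    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name.replace(".", "_"), module)
        return module

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Tensor]":
        out: "OrderedDict[str, Tensor]" = OrderedDict()
        for k, v in self._params.items():
            out[prefix + k] = v
        for mk, m in self._modules.items():
            out.update(m.named_parameters(prefix + mk + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for k, v in self._buffers.items():
            out[prefix + k] = v
        for mk, m in self._modules.items():
            out.update(m.named_buffers(prefix + mk + "."))
        return out

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for m in self._modules.values():
            m.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data for k, v in self.named_parameters().items()}
        for k, v in self.named_buffers().items():
            out["buffer." + k] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        for k, v in state.items():
            if k.startswith("buffer."):
                buf = buffers[k[len("buffer.") :]]
                buf[...] = v
            else:
                p = params[k]
                if p.data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {v.shape}")
                p.data = v.astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * k * k
        self.weight = Tensor(he_uniform(rng, (c_out, c_in, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """2x2 stride-2 up-convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_uniform(rng, (c_in, c_out, 2, 2), c_in * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias)


class Conv1d(Module):
    """Single-channel same-padded 1-D convolution (context generators)."""

    def __init__(self, k: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_uniform(rng, (k,), k), requires_grad=True)
        self.bias = Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(c, dtype=DTYPE))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_uniform(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.register_module(f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            if isinstance(layer, Module):
                x = layer(x)
            else:  # bare activation function
                x = layer(x)
        return x
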