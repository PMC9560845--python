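"""Layer modules over the autodiff tape.

Modules mirror the familiar torch-style contract: parameters register
automatically on attribute assignment, ``train()``/``eval()`` toggle batch
norm behaviour, and ``state_dict``/``load_state_dict`` round-trip all
parameters and running statistics by dotted name. Weight initialization is
He-style and driven entirely by an explicit ``numpy.random.Generator``, so
a model built twice from the same seed is bitwise identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data for n, p in self.named_parameters()}
        out.update({"buf:" + n: b for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            src = state[n]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {src.shape} vs {p.data.shape}")
            p.data = np.array(src, dtype=p.data.dtype)
        for n, b in self.named_buffers():
            b[...] = state["buf:" + n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"groups={groups} must divide in={in_ch} and out={out_ch}")
        self.stride, self.pad, self.groups = stride, pad, groups
        fan_in = (in_ch // groups) * k * k
        self.weight = Parameter(_he_normal(rng, (out_ch, in_ch // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.pad, self.groups)


class ConvTranspose2d(Module):
    """Stride-2, kernel-4, pad-1 defaults: exact spatial doubling."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_he_normal(rng, (in_ch, out_ch, k, k), in_ch * k * k))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(c, dtype=DTYPE))
        self.bias = Parameter(np.zeros(c, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float64))
        self.register_buffer("running_var", np.ones(c, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(
            x,
            self.weight,
            self.bias,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._seq = mods

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pool -> bottleneck MLP (reduction ``r``) -> sigmoid,
    giving one multiplicative weight per channel in (0, 1).
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"SE reduction {reduction} leaves no hidden units for {channels} channels"
            )
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def attention(self, x: Tensor) -> Tensor:
        """Per-channel weights with shape (B, C, 1, 1), each in (0, 1)."""
        b, c = x.shape[:2]
        pooled = ag.mean(x, axis=(2, 3))
        w = ag.sigmoid(self.fc2(ag.relu(self.fc1(pooled))))
        return ag.reshape(w, (b, c, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        return ag.mul(x, self.attention(x))


class ConvBNReLU(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 1,
    ):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, k, rng, stride=stride, pad=pad, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))
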