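"""Neural-network building blocks on top of the autodiff tensor.

Weight initialisation is zero-mean Gaussian with sd 0.02 (the convention for
this generator family), drawn from a caller-supplied seeded Generator so two
builds with the same seed are bit-identical.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T
from .tensor import Tensor

INIT_SD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy()) for k, v in self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    """Conv with optional built-in padding (reflect or zeros)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "reflect", bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.pad_mode = pad_mode
        self.weight = Parameter(
            rng.normal(0.0, INIT_SD, size=(out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.pad:
            x = T.pad2d(x, self.pad, mode=self.pad_mode)
        return T.conv2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, INIT_SD, size=(in_f, out_f)).astype(dtype))
        self.bias = Parameter(np.zeros(out_f, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class InstanceNorm2d(Module):
    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.instance_norm(x, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.tanh(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.upsample_nearest2x(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResnetBlock(Module):
    """pad-conv-IN-ReLU-pad-conv-IN with additive skip."""

    def __init__(self, ch: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng, dtype=dtype)
        self.norm1 = InstanceNorm2d()
        self.conv2 = Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng, dtype=dtype)
        self.norm2 = InstanceNorm2d()

    def forward(self, x: Tensor) -> Tensor:
        h = T.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h


class Adam(Module):
    """Adam with the conventional bias correction; state is serialisable."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
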