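"""Neural-network building blocks on top of the autodiff engine.

Weight initialization is fan-in-scaled uniform throughout, drawn from an
explicit ``numpy.random.Generator`` so models are reproducible bit-for-bit
from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal module container with parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        seen = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        seen = set()

        def visit(mod: "Module", path: str) -> None:
            for name, v in mod.__dict__.items():
                full = f"{path}{name}"
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append((full, v))
                elif isinstance(v, Module):
                    visit(v, full + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            out.append((f"{full}.{i}", item))
                        elif isinstance(item, Module):
                            visit(item, f"{full}.{i}.")

        visit(self, prefix)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self) -> "Module":
        for m in [self, *self.modules()]:
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in [self, *self.modules()]:
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def named_buffers(self, prefix: str = "") -> list[tuple["Module", str, str]]:
        """Non-trainable state (e.g. BN running statistics): (module, attr, path)."""
        out = []

        def visit(mod: "Module", path: str) -> None:
            for name, v in mod.__dict__.items():
                if isinstance(v, np.ndarray) and name.startswith("running_"):
                    out.append((mod, name, f"{path}{name}"))
                elif isinstance(v, Module):
                    visit(v, f"{path}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{path}{name}.{i}.")

        visit(self, prefix)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mod, attr, path in self.named_buffers():
            state[path] = getattr(mod, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        buffers = {path: (mod, attr) for mod, attr, path in self.named_buffers()}
        missing = (set(named) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on: {sorted(missing)}")
        for name, p in named.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()
        for path, (mod, attr) in buffers.items():
            setattr(mod, attr, np.asarray(state[path], dtype=np.float64).copy())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(
            _fan_in_uniform(rng, (in_features, out_features), in_features)
        )
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | tuple[int, int],
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        super().__init__()
        kh, kw = (
            (kernel_size, kernel_size)
            if isinstance(kernel_size, int)
            else kernel_size
        )
        fan_in = in_channels * kh * kw
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, kh, kw), fan_in)
        )
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm(Module):
    """Batch normalization over all axes except ``channel_axis``.

    Train mode uses batch statistics and updates exponential running
    statistics (momentum 0.1); eval mode uses the running statistics.
    """

    def __init__(self, num_features: int, channel_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.channel_axis = channel_axis
        self.momentum, self.eps = momentum, eps

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        shape = [1] * ndim
        shape[self.channel_axis] = -1
        return tuple(shape)

    def __call__(self, x: Tensor) -> Tensor:
        ax = tuple(i for i in range(x.ndim) if i != self.channel_axis % x.ndim)
        bs = self._bshape(x.ndim)
        if self.training:
            mu = x.mean(axis=ax, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=ax, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(bs))
            var = Tensor(self.running_var.reshape(bs))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(bs) + self.beta.reshape(bs)


class Dropout(Module):
    """Inverted dropout; active only in train mode, seeded per call site."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
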