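"""Network building blocks on top of :mod:`hicsr.nn.autograd`.

The module system is deliberately small: a :class:`Module` owns named
parameters (leaf tensors with ``requires_grad=True``) and child modules, and
exposes ``parameters()`` / ``state_dict()`` / ``load_state_dict()`` plus a
train/eval switch that only batch normalization consults.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batch_norm2d, conv2d


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, child in self._children.items():
            out.update(child.named_state(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"invalid checkpoint: missing arrays {sorted(missing)}")
        for key, arr in own.items():
            src = np.asarray(state[key], dtype=np.float64)
            if src.shape != arr.shape:
                raise ValueError(
                    f"invalid checkpoint: shape mismatch for {key}: "
                    f"{src.shape} vs {arr.shape}"
                )
            arr[...] = src

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def count_parameters(module: Module) -> int:
    """Total number of trainable scalars (weights, biases, BN scale/shift)."""
    return sum(p.size for p in module.parameters())


class Conv2d(Module):
    """Same-API convolution; He-style init from the module's own RNG."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None,
                 weight_scale: float | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            self.training, self.momentum, self.eps,
        )


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.swish()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))
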