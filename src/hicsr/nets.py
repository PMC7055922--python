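"""Generator and discriminator networks for contact-map enhancement.

The generator is a fully convolutional residual network: a 9x9 entry
convolution with Swish activation, a chain of residual blocks
(conv3 -> batch norm -> Swish -> conv3 -> batch norm -> additive skip), a
post-block conv3 + batch norm joined by a long skip from the entry
activation, and a 9x9 exit convolution whose output is squashed into (0, 1)
by g(x) = (tanh(x) + 1) / 2.  Stride is 1 with same-padding throughout, so
any input tile side is preserved.

The discriminator is a VGG-flavoured classifier: stages of widening strided
convolutions with Swish activations, a global average pool and a single
sigmoid score per tile ("probability of being a real high-coverage map").

Initialization follows the residual-restoration recipe: the closing batch
norm of every residual block (and of the post-block join) starts with zero
scale, so each block is exactly the identity at initialization; the entry
convolution starts as a narrow Gaussian tap plus He noise and the exit
convolution as a calibrated center tap, so the untrained generator is a
near-identity (mildly smoothing) map of its input rather than an arbitrary
random field.  Restoration networks trained from such a start converge far
faster, which matters at desk-scale step counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, GlobalAvgPool, Linear, Module, Sequential, Swish,
    Tensor, count_parameters,
)


def swish(x):
    """Elementwise x * sigmoid(x) (the beta = 1 Swish activation)."""
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.exp(-x))


def output_scale(x):
    """Elementwise (tanh(x) + 1) / 2 — maps any finite value into (0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    return (np.tanh(x) + 1.0) / 2.0


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    base_channels: int = 64
    resblock_count: int = 5
    entry_exit_kernel: int = 9
    resblock_kernel: int = 3
    init_seed: int = 0

    def __post_init__(self):
        if self.resblock_count < 1:
            raise ValueError("resblock_count must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.entry_exit_kernel % 2 == 0 or self.resblock_kernel % 2 == 0:
            raise ValueError("kernels must be odd")


@dataclass
class DiscriminatorConfig:
    in_channels: int = 1
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    conv_kernel: int = 3
    init_seed: int = 0

    def __post_init__(self):
        chans = tuple(self.stage_channels)
        if any(b <= a for a, b in zip(chans, chans[1:])):
            raise ValueError("stage_channels must be strictly increasing")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")


# Pass-through calibration: least-squares fit of (tanh(k*swish(u) + b)+1)/2
# to the identity on u in [0, 1] (entry tap ~ identity, so the exit conv
# sees approximately swish(input)).
PASS_GAIN = 3.363
PASS_BIAS = -1.080
ENTRY_TAP_SD = 0.5  # bins; the smoothing prior of the untrained generator


def _gaussian_tap(kernel: int, sd: float) -> np.ndarray:
    half = kernel // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax ** 2) / (2.0 * sd * sd))
    tap = np.outer(g, g)
    return tap / tap.sum()


class ResBlock(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, kernel, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.act = Swish()
        self.conv2 = Conv2d(channels, channels, kernel, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.bn2.gamma.data[:] = 0.0  # zero-gamma: block starts as identity

    def forward(self, x: Tensor) -> Tensor:
        h = self.act(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return x + h


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        c = cfg.base_channels
        self.entry = Conv2d(cfg.in_channels, c, cfg.entry_exit_kernel, rng=rng)
        self.entry_act = Swish()
        self.blocks = Sequential(*[
            ResBlock(c, cfg.resblock_kernel, rng)
            for _ in range(cfg.resblock_count)
        ])
        self.post_conv = Conv2d(c, c, cfg.resblock_kernel, rng=rng)
        self.post_bn = BatchNorm2d(c)
        self.post_bn.gamma.data[:] = 0.0
        self.exit = Conv2d(c, cfg.in_channels, cfg.entry_exit_kernel, rng=rng,
                           weight_scale=0.01 / c)
        # near-identity start: entry = Gaussian tap + He noise per channel,
        # exit = calibrated center tap reading the entry activation back out
        k = cfg.entry_exit_kernel
        tap = _gaussian_tap(k, ENTRY_TAP_SD)
        self.entry.weight.data[:, :, :, :] = (
            tap[None, None] + self.entry.weight.data * 0.05
        )
        self.exit.weight.data[:, :, k // 2, k // 2] += PASS_GAIN / c
        self.exit.bias.data[:] = PASS_BIAS

    def forward(self, x: Tensor) -> Tensor:
        a = self.entry_act(self.entry(x))
        h = self.blocks(a)
        h = a + self.post_bn(self.post_conv(h))  # long skip from entry
        return (self.exit(h).tanh() + 1.0) * 0.5

    @property
    def resblock_count(self) -> int:
        return self.cfg.resblock_count

    def layer_inventory(self) -> list[str]:
        names = ["conv9(entry)", "swish"]
        for k in range(self.cfg.resblock_count):
            names += [f"resblock{k + 1}[conv3,bn,swish,conv3,bn,+skip]"]
        names += ["conv3(post)", "bn", "+long-skip", "conv9(exit)",
                  "(tanh+1)/2"]
        return names


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        layers: list[Module] = []
        prev = cfg.in_channels
        for ch in cfg.stage_channels:
            layers += [Conv2d(prev, ch, cfg.conv_kernel, rng=rng), Swish(),
                       Conv2d(ch, ch, cfg.conv_kernel, stride=2, rng=rng),
                       Swish()]
            prev = ch
        self.features = Sequential(*layers)
        self.pool = GlobalAvgPool()
        self.head = Linear(prev, 1, rng=rng)

    def min_input_side(self) -> int:
        return 2 ** len(self.cfg.stage_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < self.min_input_side() or x.shape[3] < self.min_input_side():
            raise ValueError(
                f"tile too small: need side >= {self.min_input_side()}"
            )
        h = self.pool(self.features(x))
        return self.head(h).sigmoid().reshape(-1)


def build_generator(cfg: GeneratorConfig | None = None) -> Generator:
    return Generator(cfg or GeneratorConfig())


def build_discriminator(cfg: DiscriminatorConfig | None = None) -> Discriminator:
    return Discriminator(cfg or DiscriminatorConfig())


def count_trainable_parameters(net: Module) -> int:
    return count_parameters(net)
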