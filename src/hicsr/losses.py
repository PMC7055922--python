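"""Adversarial training objectives.

The generator minimizes a four-term objective

    L_G = l_MSE + alpha * l_feat + beta * l_TV + gamma * l_Ad

with default weights alpha = 0.006, beta = 2e-8, gamma = 0.001 chosen to put
the terms on a common scale.  ``l_feat`` is a perceptual loss — the mean
squared difference between fixed feature-extractor responses of predicted
and real maps; ``l_TV`` penalizes squared differences of adjacent pixels;
``l_Ad`` drives discriminator scores of generated tiles toward 1.

Two conventions here are deliberate stabilizations.  The raw adversarial
score mean(y_hat) increases as generated tiles become more realistic, so the
generator minimizes mean(1 - y_hat); and the discriminator uses standard
binary cross entropy with real-label 1 / fake-label 0, which shares its
minimizer with the unbounded sum log(y_hat) + log(1 - y) but has stable
gradients.  Both raw ("literal") forms remain available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Sequential, Swish, Tensor

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.006
    beta: float = 2e-8
    gamma: float = 0.001

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")

    def combine(self, l_mse: float, l_feat: float, l_tv: float,
                l_ad: float) -> float:
        return l_mse + self.alpha * l_feat + self.beta * l_tv + self.gamma * l_ad


@dataclass
class LossReport:
    l_mse: float
    l_vgg: float
    l_tv: float
    l_ad: float
    total: float
    d_loss: float = float("nan")


def _tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def mse_loss(pred, target) -> Tensor:
    pred, target = _tensor(pred), _tensor(target)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch in mse_loss")
    return ((pred - target) ** 2.0).mean()


def perceptual_loss(extractor, pred, target) -> Tensor:
    """MSE between fixed-extractor feature maps of pred and target."""
    pred, target = _tensor(pred), _tensor(target)
    f_pred = extractor(pred)
    f_target = extractor(target.detach() if target.requires_grad else target)
    if f_pred.shape != f_target.shape:
        raise ValueError("extractor output shape mismatch")
    return ((f_pred - f_target) ** 2.0).mean()


def tv_loss(x) -> Tensor:
    """Mean squared adjacent-pixel difference, vertical + horizontal,
    each normalized by its own pair count and averaged over the batch."""
    x = _tensor(x)
    if x.shape[-1] < 2 or x.shape[-2] < 2:
        raise ValueError("tv_loss requires tile side >= 2")
    nd = len(x.shape)
    sl_v1 = (slice(None),) * (nd - 2) + (slice(1, None), slice(None))
    sl_v0 = (slice(None),) * (nd - 2) + (slice(None, -1), slice(None))
    sl_h1 = (slice(None),) * (nd - 1) + (slice(1, None),)
    sl_h0 = (slice(None),) * (nd - 1) + (slice(None, -1),)
    v = ((x[sl_v1] - x[sl_v0]) ** 2.0).mean()
    h = ((x[sl_h1] - x[sl_h0]) ** 2.0).mean()
    return v + h


def adversarial_loss_g(d_fake, literal: bool = False) -> Tensor:
    """Generator-side adversarial term.

    Default: mean(1 - y_hat), which decreases as generated tiles are scored
    more realistic.  ``literal=True`` gives the raw mean(y_hat).
    """
    d_fake = _tensor(d_fake)
    if literal:
        return d_fake.mean()
    return (1.0 - d_fake).mean()


def discriminator_loss(d_real, d_fake, literal: bool = False) -> Tensor:
    """Discriminator objective over paired real/fake score batches.

    Default: binary cross entropy, mean of -[log(y) + log(1 - y_hat)] with
    scores clamped to [EPS, 1 - EPS].  ``literal=True`` evaluates the raw
    mean of log(y_hat) + log(1 - y) instead.
    """
    d_real, d_fake = _tensor(d_real), _tensor(d_fake)
    if d_real.shape != d_fake.shape:
        raise ValueError("paired score batches must have equal length")
    real = d_real.clip(EPS, 1.0 - EPS)
    fake = d_fake.clip(EPS, 1.0 - EPS)
    if literal:
        return (fake.log() + (1.0 - real).log()).mean()
    return -((real.log() + (1.0 - fake).log()).mean())


def generator_total_loss(pred, target, d_fake, extractor,
                         w: LossWeights = LossWeights()
                         ) -> tuple[Tensor, LossReport]:
    """Weighted four-term generator objective and its per-term report."""
    l_mse = mse_loss(pred, target)
    l_feat = (perceptual_loss(extractor, pred, target) if extractor is not None
              else Tensor(0.0))
    l_tv = tv_loss(pred)
    l_ad = adversarial_loss_g(d_fake)
    total = l_mse + w.alpha * l_feat + w.beta * l_tv + w.gamma * l_ad
    report = LossReport(
        l_mse=l_mse.item(), l_vgg=l_feat.item(), l_tv=l_tv.item(),
        l_ad=l_ad.item(), total=total.item(),
    )
    return total, report


class BuiltinExtractor(Module):
    """Fixed three-stage convolutional feature stack (frozen, seed-0 init).

    A deterministic, dependency-free perceptual reference: strided 3x3
    convolutions with Swish activations, widths 8 -> 16 -> 16.  Weights are
    never trained; gradients flow only to the input.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = (8, 16, 16)):
        super().__init__()
        rng = np.random.default_rng(seed)
        layers: list[Module] = []
        prev = 1
        for ch in channels:
            layers += [Conv2d(prev, ch, 3, stride=2, rng=rng), Swish()]
            prev = ch
        self.stack = Sequential(*layers)
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        return self.stack(x)


class IdentityExtractor(Module):
    """Pass-through extractor; collapses the perceptual loss onto MSE."""

    def forward(self, x: Tensor) -> Tensor:
        return x


def make_extractor(name: str):
    """'builtin' -> frozen conv stack; 'identity' -> pass-through;
    'none' -> None (perceptual term dropped)."""
    if name == "builtin":
        return BuiltinExtractor()
    if name == "identity":
        return IdentityExtractor()
    if name in ("none", ""):
        return None
    raise ValueError(f"unknown extractor: {name!r}")
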