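"""Alternating adversarial training on paired (low-coverage, truth) tiles.

Each batch updates the discriminator once on (real, detached fake) scores
and then the generator once through the four-term objective, both with Adam
at the configured learning rate.  After every epoch the generator is
evaluated on the held-out chromosomes: mean per-term loss, mean tile SSIM
and mean tile PSNR against the truth tiles.  Chromosome-level train/test
separation is enforced, and a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ContactMatrix
from .losses import (
    LossReport, LossWeights, adversarial_loss_g, discriminator_loss,
    generator_total_loss, make_extractor,
)
from .metrics import psnr, ssim
from .nets import (
    Discriminator, DiscriminatorConfig, Generator, GeneratorConfig,
    build_discriminator, build_generator,
)
from .nn import Adam, Tensor
from .preprocess import TileSet, clip_scale, resolve_cutoff, tile
from .simulate import DownsampleRatio


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 200
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    extractor: str = "builtin"
    train_chroms: list[str] = field(default_factory=list)
    test_chroms: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class PairedTiles:
    """Coordinate-aligned (input, target) tile pairs for one chromosome."""

    chrom: str
    x: np.ndarray  # (N, 1, t, t) low-coverage scaled tiles
    y: np.ndarray  # (N, 1, t, t) truth scaled tiles
    coords: list[tuple[int, int]]
    input_cutoff: float
    target_cutoff: float

    def __post_init__(self):
        if self.x.shape != self.y.shape:
            raise ValueError("paired tile stacks must have equal shape")


@dataclass
class EpochRecord:
    epoch: int
    d_loss: float
    train: LossReport
    test: LossReport
    test_ssim: float
    test_psnr: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def test_ssim_trace(self) -> list[float]:
        return [r.test_ssim for r in self.records]

    def test_loss_trace(self) -> list[float]:
        return [r.test.total for r in self.records]


def make_pairs(low: ContactMatrix, truth: ContactMatrix,
               ratio: DownsampleRatio | float | None,
               tile_size: int = 40, band_bp: int = 2_000_000) -> PairedTiles:
    """Scale and tile a (downsampled, truth) chromosome pair."""
    in_cut = resolve_cutoff(low, "input", ratio)
    tg_cut = resolve_cutoff(truth, "target", None)
    ts_x = tile(clip_scale(low, in_cut), tile_size, band_bp)
    ts_y = tile(clip_scale(truth, tg_cut), tile_size, band_bp)
    if ts_x.coords != ts_y.coords:
        raise ValueError("paired tiles are not coordinate-aligned")
    return PairedTiles(chrom=truth.chrom, x=ts_x.stack(), y=ts_y.stack(),
                       coords=ts_x.coords, input_cutoff=in_cut,
                       target_cutoff=tg_cut)


def _gather(pairs: list[PairedTiles]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise ValueError("empty tile set")
    x = np.concatenate([p.x for p in pairs])
    y = np.concatenate([p.y for p in pairs])
    return x, y


def _mean_report(reports: list[LossReport]) -> LossReport:
    return LossReport(
        l_mse=float(np.mean([r.l_mse for r in reports])),
        l_vgg=float(np.mean([r.l_vgg for r in reports])),
        l_tv=float(np.mean([r.l_tv for r in reports])),
        l_ad=float(np.mean([r.l_ad for r in reports])),
        total=float(np.mean([r.total for r in reports])),
    )


def evaluate_tiles(g: Generator, d: Discriminator | None, x: np.ndarray,
                   y: np.ndarray, extractor, w: LossWeights,
                   batch_size: int = 64) -> tuple[LossReport, float, float]:
    """Mean loss report, SSIM and PSNR of enhanced vs truth tiles."""
    g.eval()
    if d is not None:
        d.eval()
    reports, ssims, psnrs = [], [], []
    for lo in range(0, x.shape[0], batch_size):
        xb = Tensor(x[lo:lo + batch_size])
        yb = Tensor(y[lo:lo + batch_size])
        pred = g(xb)
        if d is not None:
            scores = d(pred.detach())
        else:
            scores = Tensor(np.ones(xb.shape[0]))
        _, rep = generator_total_loss(pred.detach(), yb, scores.detach(),
                                      extractor, w)
        reports.append(rep)
        for i in range(pred.data.shape[0]):
            ssims.append(ssim(pred.data[i, 0], yb.data[i, 0]))
            psnrs.append(psnr(pred.data[i, 0], yb.data[i, 0]))
    finite = [p for p in psnrs if np.isfinite(p)]
    return (_mean_report(reports), float(np.mean(ssims)),
            float(np.mean(finite)) if finite else float("inf"))


def train(g_cfg: GeneratorConfig, d_cfg: DiscriminatorConfig,
          tiles_train: list[PairedTiles], tiles_test: list[PairedTiles],
          cfg: TrainConfig) -> tuple[Generator, Discriminator, TrainHistory]:
    """Adversarial training; deterministic for a fixed config + seed."""
    train_chroms = {p.chrom for p in tiles_train}
    test_chroms = {p.chrom for p in tiles_test}
    if train_chroms & test_chroms:
        raise ValueError(
            f"train/test chromosomes overlap: {sorted(train_chroms & test_chroms)}"
        )
    if cfg.train_chroms and not train_chroms <= set(cfg.train_chroms):
        raise ValueError("training tiles from undeclared chromosomes")
    if cfg.test_chroms and not test_chroms <= set(cfg.test_chroms):
        raise ValueError("test tiles from undeclared chromosomes")
    x_train, y_train = _gather(tiles_train)
    x_test, y_test = _gather(tiles_test)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")

    g = Generator(GeneratorConfig(**{**asdict(g_cfg),
                                     "init_seed": cfg.seed}))
    d = Discriminator(DiscriminatorConfig(**{**asdict(d_cfg),
                                             "init_seed": cfg.seed + 1}))
    extractor = make_extractor(cfg.extractor)
    opt_g = Adam(g.parameters(), lr=cfg.learning_rate)
    opt_d = Adam(d.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    n = x_train.shape[0]

    for epoch in range(1, cfg.epochs + 1):
        g.train()
        d.train()
        order = rng.permutation(n)
        d_losses, g_reports = [], []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = Tensor(x_train[idx])
            yb = Tensor(y_train[idx])
            fake = g(xb)
            # -- discriminator step on (real, detached fake)
            opt_d.zero_grad()
            d_real = d(yb)
            d_fake = d(fake.detach())
            l_d = discriminator_loss(d_real, d_fake)
            l_d.backward()
            opt_d.step()
            # -- generator step through fresh discriminator scores
            opt_g.zero_grad()
            d_fake2 = d(fake)
            total, rep = generator_total_loss(fake, yb, d_fake2, extractor,
                                              cfg.loss_weights)
            if not np.isfinite(total.item()):
                raise RuntimeError(f"diverged at epoch {epoch}")
            total.backward()
            opt_g.step()
            d_losses.append(l_d.item())
            rep.d_loss = l_d.item()
            g_reports.append(rep)
        test_rep, test_ssim, test_psnr = evaluate_tiles(
            g, d, x_test, y_test, extractor, cfg.loss_weights, cfg.batch_size
        )
        history.records.append(EpochRecord(
            epoch=epoch, d_loss=float(np.mean(d_losses)),
            train=_mean_report(g_reports), test=test_rep,
            test_ssim=test_ssim, test_psnr=test_psnr,
        ))
    g.eval()
    d.eval()
    return g, d, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(g: Generator, d: Discriminator | None,
                    history: TrainHistory | None, path: str,
                    train_cfg: TrainConfig | None = None,
                    cutoffs: dict | None = None) -> None:
    """Single-file archive: configs + weights + training manifest."""
    manifest = {
        "g_cfg": asdict(g.cfg),
        "d_cfg": asdict(d.cfg) if d is not None else None,
        "train_cfg": (
            {**asdict(train_cfg),
             "loss_weights": asdict(train_cfg.loss_weights)}
            if train_cfg is not None else None
        ),
        "cutoffs": cutoffs or {},
        "history": (
            [{"epoch": r.epoch, "d_loss": r.d_loss,
              "train": asdict(r.train), "test": asdict(r.test),
              "test_ssim": r.test_ssim, "test_psnr": r.test_psnr}
             for r in history.records] if history is not None else []
        ),
    }
    arrays = {"g." + k: v for k, v in g.state_dict().items()}
    if d is not None:
        arrays.update({"d." + k: v for k, v in d.state_dict().items()})
    np.savez(path, manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str, g_cfg: GeneratorConfig | None = None
                    ) -> tuple[Generator, Discriminator | None, dict]:
    """Restore models and manifest; an explicitly passed ``g_cfg`` must match
    the stored one."""
    try:
        with np.load(path) as archive:
            manifest = json.loads(bytes(archive["manifest"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "manifest"}
    except (OSError, KeyError, ValueError) as exc:
        raise ValueError(f"invalid checkpoint: {exc}") from exc
    stored_g = GeneratorConfig(**manifest["g_cfg"])
    if g_cfg is not None and asdict(g_cfg) != asdict(stored_g):
        raise ValueError("invalid checkpoint: generator config mismatch")
    g = build_generator(stored_g)
    g.load_state_dict({k[2:]: v for k, v in arrays.items()
                       if k.startswith("g.")})
    g.eval()
    d = None
    if manifest.get("d_cfg"):
        d_cfg = manifest["d_cfg"]
        d_cfg["stage_channels"] = tuple(d_cfg["stage_channels"])
        d = build_discriminator(DiscriminatorConfig(**d_cfg))
        d.load_state_dict({k[2:]: v for k, v in arrays.items()
                           if k.startswith("d.")})
        d.eval()
    return g, d, manifest
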