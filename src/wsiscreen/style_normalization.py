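"""Cycle-GAN style normalization between scanner domains.

Two U-Net generators (A->B and B->A, tanh output on [-1, 1]-scaled
images) and two least-squares patch discriminators are
trained on unpaired tissue patches from the two domains.  The generator
objective is the adversarial terms weighted by ``lambda_disc`` (reference
1.0) plus cycle-consistency L1 terms weighted by ``lambda_cycle``
(reference 10.0).  The trained source->target generator is applied to
whole slides with an overlapped sliding window and linear ramp blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wasserstein_distance
from skimage.transform import resize

from . import _nn
from ._nn import AvgPool2, Conv2d, LeakyReLU, Sequential, l1_loss, lsgan_loss
from .segmentation_models import UNet, UNetConfig
from .wsi_io import SlidePyramid, TissueMask

__all__ = [
    "CycleGanConfig",
    "DomainPair",
    "sample_training_patches",
    "train_cyclegan",
    "normalize_slide",
    "domain_gap",
]


@dataclass
class CycleGanConfig:
    lambda_cycle: float = 10.0
    lambda_disc: float = 1.0
    patch_size: int = 256
    epochs: int = 150
    iterations_per_epoch: int = 50
    batch_size: int = 4
    lr: float = 0.0005
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 20
    n_slides_per_domain: int = 5
    # architecture scale (desk-size models use small values)
    gen_depth: int = 4
    gen_filters: int = 16
    disc_filters: int = 16
    scale_range: tuple[float, float] = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_cycle", "lambda_disc", "patch_size", "epochs",
                     "iterations_per_epoch", "batch_size", "lr", "lr_decay_every",
                     "n_slides_per_domain", "gen_depth", "gen_filters", "disc_filters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")

    def lr_at(self, epoch: int) -> float:
        """Step-decay schedule: lr * factor^(epoch // decay_every)."""
        return self.lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class DomainPair:
    g_ab: UNet
    g_ba: UNet
    d_a: Sequential
    d_b: Sequential
    history: dict = field(default_factory=dict)
    cfg: CycleGanConfig | None = None


def _build_generator(cfg: CycleGanConfig, seed: int) -> UNet:
    ucfg = UNetConfig(depth=cfg.gen_depth, base_filters=cfg.gen_filters,
                      spatial_dropout=0.0, n_classes=3, in_channels=3,
                      input_size=cfg.patch_size
                      if cfg.patch_size % 2 ** (cfg.gen_depth - 1) == 0
                      else 2 ** (cfg.gen_depth - 1),
                      seed=seed)
    # no feature normalization: per-patch instance statistics destroy the
    # absolute color identity the translation must preserve at small patch sizes
    return UNet(ucfg, out_channels=3, final="tanh", norm="none",
                input_range="symmetric")


def _build_discriminator(cfg: CycleGanConfig, seed: int) -> Sequential:
    rng = np.random.default_rng(seed)
    f = cfg.disc_filters
    return Sequential(
        Conv2d(3, f, 3, rng=rng), LeakyReLU(0.2), AvgPool2(),
        Conv2d(f, 2 * f, 3, rng=rng), LeakyReLU(0.2), AvgPool2(),
        Conv2d(2 * f, 4 * f, 3, rng=rng), LeakyReLU(0.2),
        Conv2d(4 * f, 1, 3, rng=rng),
    )


def _to_unit(x: np.ndarray) -> np.ndarray:
    return x.astype(np.float32) / 127.5 - 1.0


def _from_unit(y: np.ndarray) -> np.ndarray:
    return np.clip(np.rint((y + 1.0) * 127.5), 0, 255).astype(np.uint8)


# --------------------------------------------------------------- sampling

def sample_training_patches(slides: list[SlidePyramid], tissue_masks: list[TissueMask],
                            cfg: CycleGanConfig, rng, n: int = 1,
                            augment: bool = True) -> np.ndarray:
    """Draw n tissue-centered patches (uint8, patch_size square) from a domain.

    Patch centers are uniform over tissue-mask pixels pooled across the
    domain's slides; rotation/mirroring and isotropic scaling augmentations
    are applied when ``augment`` is set.  Deterministic given the rng state.
    """
    coords = []
    for i, (slide, tm) in enumerate(zip(slides, tissue_masks)):
        ys, xs = np.nonzero(tm.mask)
        if ys.size:
            coords.append((i, ys, xs))
    if not coords:
        raise ValueError("no tissue pixels in any slide of the domain")

    ps = cfg.patch_size
    out = np.empty((n, ps, ps, 3), dtype=np.uint8)
    for k in range(n):
        i, ys, xs = coords[rng.integers(len(coords))]
        arr = slides[i].level_array(0)
        h, w = arr.shape[:2]
        scale = rng.uniform(*cfg.scale_range) if augment else 1.0
        foot = max(8, int(round(ps * scale)))
        j = rng.integers(ys.size)
        cy = int(np.clip(ys[j], foot // 2, h - (foot - foot // 2)))
        cx = int(np.clip(xs[j], foot // 2, w - (foot - foot // 2)))
        tile = arr[cy - foot // 2 : cy - foot // 2 + foot,
                   cx - foot // 2 : cx - foot // 2 + foot]
        if foot != ps:
            tile = np.clip(np.rint(resize(tile.astype(float), (ps, ps, 3),
                                          anti_aliasing=foot > ps)), 0, 255).astype(np.uint8)
        if augment:
            k_rot = int(rng.integers(4))
            if k_rot:
                tile = np.rot90(tile, k=k_rot)
            if rng.random() < 0.5:
                tile = tile[:, ::-1]
        out[k] = tile
    return out


# ---------------------------------------------------------------- training

def train_cyclegan(domain_a, domain_b, cfg: CycleGanConfig) -> DomainPair:
    """Train the generator/discriminator quartet on unpaired patch arrays.

    ``domain_a``/``domain_b`` are uint8 patch stacks (N, ps, ps, 3) or
    callables ``f(rng, batch_size) -> stack`` streaming fresh patches.
    Per-epoch component losses (cycle, adversarial, their weighted total,
    discriminator) are recorded in history; training aborts on NaN.
    """
    rng = np.random.default_rng(cfg.seed)
    g_ab = _build_generator(cfg, seed=int(rng.integers(2**31)))
    g_ba = _build_generator(cfg, seed=int(rng.integers(2**31)))
    d_a = _build_discriminator(cfg, seed=int(rng.integers(2**31)))
    d_b = _build_discriminator(cfg, seed=int(rng.integers(2**31)))

    gen_params = g_ab.params() + g_ba.params()
    disc_params = d_a.params() + d_b.params()
    gen_opt = _nn.Adam(gen_params, lr=cfg.lr)
    disc_opt = _nn.Adam(disc_params, lr=cfg.lr)

    def _batch(domain):
        if callable(domain):
            return _to_unit(domain(rng, cfg.batch_size))
        idx = rng.integers(0, len(domain), size=cfg.batch_size)
        return _to_unit(np.asarray(domain)[idx])

    history = {"cycle": [], "adversarial": [], "gen_total": [], "disc": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        gen_opt.lr = disc_opt.lr = lr
        ep = {"cycle": 0.0, "adversarial": 0.0, "gen_total": 0.0, "disc": 0.0}
        for _ in range(cfg.iterations_per_epoch):
            x_a = _batch(domain_a)
            x_b = _batch(domain_b)

            # ---- generator update (adversarial + cycle terms)
            gen_opt.zero_grad()
            fake_b = g_ab.forward(x_a, train=True)
            pred = d_b.forward(fake_b, train=True)
            l_adv_ab, dpred = lsgan_loss(pred, 1.0)
            g_fake_b = d_b.backward(dpred * cfg.lambda_disc)
            rec_a = g_ba.forward(fake_b, train=True)
            l_cyc_a, drec = l1_loss(rec_a, x_a)
            g_fake_b = g_fake_b + g_ba.backward(drec * cfg.lambda_cycle)
            g_ab.backward(g_fake_b)

            fake_a = g_ba.forward(x_b, train=True)
            pred = d_a.forward(fake_a, train=True)
            l_adv_ba, dpred = lsgan_loss(pred, 1.0)
            g_fake_a = d_a.backward(dpred * cfg.lambda_disc)
            rec_b = g_ab.forward(fake_a, train=True)
            l_cyc_b, drec = l1_loss(rec_b, x_b)
            g_fake_a = g_fake_a + g_ab.backward(drec * cfg.lambda_cycle)
            g_ba.backward(g_fake_a)

            # discriminator grads polluted by the generator pass: clear them
            for p in disc_params:
                p.grad[...] = 0.0
            gen_opt.step()

            # ---- discriminator update on real/fake (generators frozen)
            disc_opt.zero_grad()
            l_d = 0.0
            for disc, real, fake in ((d_b, x_b, fake_b), (d_a, x_a, fake_a)):
                pr = disc.forward(real, train=True)
                lr_, dd = lsgan_loss(pr, 1.0)
                disc.backward(dd * 0.5)
                pf = disc.forward(fake, train=True)
                lf_, dd = lsgan_loss(pf, 0.0)
                disc.backward(dd * 0.5)
                l_d += 0.5 * (lr_ + lf_)
            disc_opt.step()

            cyc = l_cyc_a + l_cyc_b
            adv = l_adv_ab + l_adv_ba
            total = cfg.lambda_cycle * cyc + cfg.lambda_disc * adv
            if not np.isfinite(total) or not np.isfinite(l_d):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            ep["cycle"] += cyc
            ep["adversarial"] += adv
            ep["gen_total"] += total
            ep["disc"] += l_d
        for k_ in ep:
            history[k_].append(ep[k_] / cfg.iterations_per_epoch)
        history["lr"].append(lr)

    return DomainPair(g_ab=g_ab, g_ba=g_ba, d_a=d_a, d_b=d_b,
                      history=history, cfg=cfg)


# ------------------------------------------------------------- application

def apply_generator(generator, patches: np.ndarray) -> np.ndarray:
    """Run uint8 patches through a generator, back to uint8."""
    return _from_unit(generator.forward(_to_unit(np.asarray(patches)), train=False))


def normalize_slide(slide: SlidePyramid, generator, tissue_mask: TissueMask,
                    tile_size: int = 256, overlap: int = 32,
                    tissue_threshold: float = 0.05, batch_size: int = 16) -> SlidePyramid:
    """Sliding-window slide translation with linear ramp blending.

    Tiles overlapping tissue are translated by the generator and blended
    with a linear ramp over the ``overlap`` margin; tiles without tissue
    pass through unchanged (a blank slide is returned untouched with zero
    generator calls).  The output pyramid keeps the input geometry.
    """
    arr = slide.level_array(0)
    h, w = arr.shape[:2]
    mask = tissue_mask.mask
    if tissue_mask.level != 0 or mask.shape != (h, w):
        raise ValueError("tissue mask must be at level 0 with slide geometry")
    if overlap >= tile_size:
        raise ValueError("overlap must be smaller than tile_size")

    # separable linear ramp window
    ramp = np.ones(tile_size)
    if overlap > 0:
        r = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
        ramp[:overlap] = r
        ramp[-overlap:] = r[::-1]
    window = np.outer(ramp, ramp)[..., None].astype(np.float32)

    acc = np.zeros((h, w, 3), dtype=np.float32)
    wacc = np.zeros((h, w, 1), dtype=np.float32)
    step = tile_size - overlap

    tiles, coords = [], []

    def _flush():
        if not tiles:
            return
        out = apply_generator(generator, np.stack(tiles)).astype(np.float32)
        for t, (ty, tx, th, tw) in enumerate(coords):
            acc[ty : ty + th, tx : tx + tw] += out[t, :th, :tw] * window[:th, :tw]
            wacc[ty : ty + th, tx : tx + tw] += window[:th, :tw]
        tiles.clear()
        coords.clear()

    for ty in range(0, h, step):
        for tx in range(0, w, step):
            th = min(tile_size, h - ty)
            tw = min(tile_size, w - tx)
            if mask[ty : ty + th, tx : tx + tw].mean() < tissue_threshold:
                continue
            tile = arr[ty : ty + th, tx : tx + tw]
            if th < tile_size or tw < tile_size:
                tile = np.pad(tile, ((0, tile_size - th), (0, tile_size - tw), (0, 0)),
                              mode="reflect")
            tiles.append(tile)
            coords.append((ty, tx, th, tw))
            if len(tiles) >= batch_size:
                _flush()
    _flush()

    out = arr.astype(np.float32).copy()
    covered = wacc[..., 0] > 0
    out[covered] = acc[covered] / wacc[covered]
    out8 = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    level1 = np.clip(np.rint(resize(out8.astype(float), (h // 2, w // 2, 3),
                                    anti_aliasing=True)), 0, 255).astype(np.uint8)
    return SlidePyramid([out8, level1], mpp_x=slide.mpp_x, mpp_y=slide.mpp_y,
                        slide_id=slide.slide_id)


# ------------------------------------------------------------- domain gap

def domain_gap(patches_a: np.ndarray, patches_b: np.ndarray) -> float:
    """Mean per-channel Wasserstein-1 distance between intensity distributions.

    Symmetric; zero iff the empirical per-channel pixel distributions
    coincide.  A constant +d shift of one channel yields d/3.
    """
    a = np.asarray(patches_a, dtype=np.float64)
    b = np.asarray(patches_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both patch sets must be nonempty")
    gaps = [wasserstein_distance(a[..., c].ravel(), b[..., c].ravel()) for c in range(3)]
    return float(np.mean(gaps))
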