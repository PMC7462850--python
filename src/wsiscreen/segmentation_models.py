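"""Segmentation and patch-classification models, with seeded SGD training.

Three families are provided:

* ``build_unet`` -- encoder/decoder U-Net; the reference configuration is
  5 levels deep with 64..1024 filters, spatial dropout 0.25 and same-padded
  convolutions so the class map matches the input size.
* ``build_densenet_fcn`` -- a fully-convolutional DenseNet whose dense
  blocks concatenate every preceding layer's feature maps (reference: 5
  dense blocks, growth 16, 4 layers per block, 256-px input).
* ``build_patch_classifier`` -- a small width-scalable CNN emitting one
  probability vector per patch.

All sizes scale down through the configs so the same code trains at desk
scale on CPU.  Training uses stochastic gradient descent with categorical
cross-entropy (batch size 3, learning rate 5e-4 by default), monitors a
validation metric, and restores the best-epoch weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (
    Conv2d,
    Dense,
    GlobalAvgPool,
    InstanceNorm,
    Layer,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    SpatialDropout,
    Tanh,
    Upsample2,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "UNetConfig",
    "DenseFCNConfig",
    "PatchClassifierConfig",
    "TrainConfig",
    "UNet",
    "DenseNetFCN",
    "PatchClassifier",
    "build_unet",
    "build_densenet_fcn",
    "build_patch_classifier",
    "train",
]


@dataclass
class UNetConfig:
    depth: int = 5
    base_filters: int = 64
    spatial_dropout: float = 0.25
    n_classes: int = 5
    input_size: int = 512
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not 0.0 <= self.spatial_dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}")

    @property
    def filters(self) -> list[int]:
        return [self.base_filters * 2**i for i in range(self.depth)]


@dataclass
class DenseFCNConfig:
    dense_blocks: int = 5
    growth: int = 16
    layers_per_block: int = 4
    init_filters: int = 48
    n_classes: int = 5
    input_size: int = 256
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("dense_blocks", "growth", "layers_per_block", "init_filters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dense_blocks % 2 == 0:
            raise ValueError("dense_blocks must be odd (down blocks + bottleneck + up blocks)")

    @property
    def n_down(self) -> int:
        return (self.dense_blocks - 1) // 2


@dataclass
class PatchClassifierConfig:
    width: int = 16
    n_blocks: int = 3
    n_classes: int = 5
    input_size: int = 64
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.width < 1 or self.n_blocks < 1:
            raise ValueError("width and n_blocks must be positive")


@dataclass
class TrainConfig:
    batch_size: int = 3
    learning_rate: float = 0.0005
    momentum: float = 0.9
    max_epochs: int = 100
    patience: int = 10
    monitor: str = "val_loss"  # val_loss | val_dice | val_accuracy
    clip_norm: float | None = 5.0  # global gradient-norm cap; None disables
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


# ------------------------------------------------------------------ U-Net

class _ConvBlock(Layer):
    """conv-act-conv-act with optional instance norm and spatial dropout."""

    def __init__(self, cin, cout, rng, dropout=0.0, norm="none", act=ReLU):
        layers: list[Layer] = [Conv2d(cin, cout, 3, rng=rng)]
        if norm == "instance":
            layers.append(InstanceNorm(cout))
        layers.append(act())
        layers.append(Conv2d(cout, cout, 3, rng=rng))
        if norm == "instance":
            layers.append(InstanceNorm(cout))
        layers.append(act())
        if dropout > 0:
            layers.append(SpatialDropout(dropout, rng=np.random.default_rng(rng.integers(2**31))))
        self.seq = Sequential(*layers)

    def forward(self, x, train=False):
        return self.seq.forward(x, train=train)

    def backward(self, dy):
        return self.seq.backward(dy)

    def params(self):
        return self.seq.params()


class UNet:
    """Same-padding U-Net; per-pixel softmax class probabilities.

    ``final='tanh'`` with ``out_channels=3`` turns the same backbone into
    the style-transfer generator used by the cycle-GAN module.
    """

    def __init__(self, cfg: UNetConfig, out_channels: int | None = None,
                 final: str = "logits", norm: str = "none",
                 input_range: str = "unit"):
        self.cfg = cfg
        self.final = final
        # "unit": callers pass [0,1] images, centered to [-1,1] internally
        # (a norm-free net trains far more reliably on zero-mean input);
        # "symmetric": input is already [-1,1] (the GAN generators).
        self.input_range = input_range
        rng = np.random.default_rng(cfg.seed)
        f = cfg.filters
        out_ch = out_channels if out_channels is not None else cfg.n_classes
        self.out_channels = out_ch

        self.enc = []
        cin = cfg.in_channels
        for i in range(cfg.depth):
            drop = cfg.spatial_dropout if i < cfg.depth else 0.0
            self.enc.append(_ConvBlock(cin, f[i], rng, dropout=drop, norm=norm))
            cin = f[i]
        self.pools = [MaxPool2() for _ in range(cfg.depth - 1)]

        self.up_convs = []   # 3x3 conv after upsampling, halving channels
        self.dec = []
        for i in range(cfg.depth - 2, -1, -1):
            self.up_convs.append(Conv2d(f[i + 1], f[i], 3, rng=rng))
            self.dec.append(_ConvBlock(2 * f[i], f[i], rng, norm=norm))
        self.head = Conv2d(f[0], out_ch, 1, rng=rng)
        self.out_act = Tanh() if final == "tanh" else None

    def forward(self, x, train=False):
        d = 2 ** (self.cfg.depth - 1)
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(f"input spatial size must be divisible by {d}")
        if self.input_range == "unit":
            x = x * 2.0 - 1.0
        skips = []
        for i in range(self.cfg.depth - 1):
            x = self.enc[i].forward(x, train=train)
            skips.append(x)
            x = self.pools[i].forward(x, train=train)
        x = self.enc[-1].forward(x, train=train)
        self._ups = [Upsample2() for _ in range(self.cfg.depth - 1)]
        for j in range(self.cfg.depth - 1):
            x = self._ups[j].forward(x, train=train)
            x = self.up_convs[j].forward(x, train=train)
            skip = skips[-(j + 1)]
            x = np.concatenate([skip, x], axis=-1)
            x = self.dec[j].forward(x, train=train)
        x = self.head.forward(x, train=train)
        if self.out_act is not None:
            x = self.out_act.forward(x, train=train)
        return x

    def backward(self, dy):
        if self.out_act is not None:
            dy = self.out_act.backward(dy)
        dy = self.head.backward(dy)
        dskips = []
        for j in range(self.cfg.depth - 2, -1, -1):
            dy = self.dec[j].backward(dy)
            c = self.cfg.filters[self.cfg.depth - 2 - j]
            dskip, dy = dy[..., :c], dy[..., c:]
            dskips.append(dskip)  # for skip at level depth-2-j
            dy = self.up_convs[j].backward(dy)
            dy = self._ups[j].backward(dy)
        dy = self.enc[-1].backward(dy)
        for i in range(self.cfg.depth - 2, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]  # dskips[k] holds the level-k skip gradient
            dy = self.enc[i].backward(dy)
        return dy * 2.0 if self.input_range == "unit" else dy

    def params(self):
        ps = []
        for b in self.enc:
            ps += b.params()
        for c in self.up_convs:
            ps += c.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def predict_proba(self, x):
        out = self.forward(x, train=False)
        return softmax(out) if self.final == "logits" else out


def build_unet(cfg: UNetConfig) -> UNet:
    return UNet(cfg)


# ------------------------------------------------------------- DenseNetFCN

class _DenseBlock(Layer):
    """Dense block: each 3x3 conv layer consumes the concat of everything before it."""

    def __init__(self, cin, growth, n_layers, rng):
        self.cin, self.growth, self.n_layers = cin, growth, n_layers
        self.convs = [Conv2d(cin + j * growth, growth, 3, rng=rng) for j in range(n_layers)]
        self.acts = [ReLU() for _ in range(n_layers)]

    @property
    def cout(self):
        return self.cin + self.n_layers * self.growth

    def forward(self, x, train=False):
        feats = [x]
        for conv, act in zip(self.convs, self.acts):
            inp = np.concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
            feats.append(act.forward(conv.forward(inp, train=train), train=train))
        return np.concatenate(feats, axis=-1)

    def backward(self, dy):
        widths = [self.cin] + [self.growth] * self.n_layers
        splits = np.cumsum(widths)[:-1]
        grads = list(np.split(dy, splits, axis=-1))  # d wrt x, y1..yL
        for j in range(self.n_layers - 1, -1, -1):
            dyj = grads[j + 1]
            din = self.convs[j].backward(self.acts[j].backward(dyj))
            in_widths = [self.cin] + [self.growth] * j
            parts = np.split(din, np.cumsum(in_widths)[:-1], axis=-1)
            for k, part in enumerate(parts):
                grads[k] = grads[k] + part
        return grads[0]

    def params(self):
        return [p for c in self.convs for p in c.params()]


class DenseNetFCN:
    """Fully-convolutional DenseNet: dense blocks on a down/up path."""

    def __init__(self, cfg: DenseFCNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = Conv2d(cfg.in_channels, cfg.init_filters, 3, rng=rng)
        self.down_blocks, self.down_trans, self.pools = [], [], []
        c = cfg.init_filters
        skip_channels = []
        for _ in range(cfg.n_down):
            db = _DenseBlock(c, cfg.growth, cfg.layers_per_block, rng)
            self.down_blocks.append(db)
            skip_channels.append(db.cout)
            self.down_trans.append(Conv2d(db.cout, db.cout, 1, rng=rng))
            self.pools.append(MaxPool2())
            c = db.cout
        self.bottleneck = _DenseBlock(c, cfg.growth, cfg.layers_per_block, rng)
        c = self.bottleneck.cout
        self.up_convs, self.up_blocks = [], []
        for i in range(cfg.n_down):
            sc = skip_channels[-(i + 1)]
            self.up_convs.append(Conv2d(c, sc, 3, rng=rng))
            db = _DenseBlock(2 * sc, cfg.growth, cfg.layers_per_block, rng)
            self.up_blocks.append(db)
            c = db.cout
        self.head = Conv2d(c, cfg.n_classes, 1, rng=rng)
        self.final = "logits"
        self._skip_channels = skip_channels

    def forward(self, x, train=False):
        d = 2 ** self.cfg.n_down
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(f"input spatial size must be divisible by {d}")
        x = self.stem.forward(x * 2.0 - 1.0, train=train)
        skips = []
        for db, tr, pool in zip(self.down_blocks, self.down_trans, self.pools):
            x = db.forward(x, train=train)
            skips.append(x)
            x = pool.forward(tr.forward(x, train=train), train=train)
        x = self.bottleneck.forward(x, train=train)
        self._ups = [Upsample2() for _ in range(self.cfg.n_down)]
        for j in range(self.cfg.n_down):
            x = self._ups[j].forward(x, train=train)
            x = self.up_convs[j].forward(x, train=train)
            x = np.concatenate([skips[-(j + 1)], x], axis=-1)
            x = self.up_blocks[j].forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dy):
        dy = self.head.backward(dy)
        dskips = {}
        for j in range(self.cfg.n_down - 1, -1, -1):
            dy = self.up_blocks[j].backward(dy)
            sc = self._skip_channels[-(j + 1)]
            dskips[self.cfg.n_down - 1 - j] = dy[..., :sc]
            dy = self.up_convs[j].backward(dy[..., sc:])
            dy = self._ups[j].backward(dy)
        dy = self.bottleneck.backward(dy)
        for i in range(self.cfg.n_down - 1, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = self.down_trans[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.down_blocks[i].backward(dy)
        return self.stem.backward(dy)

    def params(self):
        ps = self.stem.params()
        for db, tr in zip(self.down_blocks, self.down_trans):
            ps += db.params() + tr.params()
        ps += self.bottleneck.params()
        for c, db in zip(self.up_convs, self.up_blocks):
            ps += c.params() + db.params()
        return ps + self.head.params()

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))


def build_densenet_fcn(cfg: DenseFCNConfig) -> DenseNetFCN:
    return DenseNetFCN(cfg)


# -------------------------------------------------------- patch classifier

class PatchClassifier:
    """Small conv-pool CNN with a global-average-pool softmax head."""

    def __init__(self, cfg: PatchClassifierConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers: list[Layer] = []
        cin = cfg.in_channels
        self.conv_layers = []
        for i in range(cfg.n_blocks):
            cout = cfg.width * 2**i
            conv = Conv2d(cin, cout, 3, rng=rng)
            self.conv_layers.append(conv)
            layers += [conv, ReLU(), MaxPool2()]
            cin = cout
        layers.append(GlobalAvgPool())
        self.seq = Sequential(*layers)
        self.dense = Dense(cin, cfg.n_classes, rng=rng)
        self.final = "logits"

    def forward(self, x, train=False):
        return self.dense.forward(self.seq.forward(x * 2.0 - 1.0, train=train), train=train)

    def backward(self, dy):
        return self.seq.backward(self.dense.backward(dy))

    def params(self):
        return self.seq.params() + self.dense.params()

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def n_conv_parameters(self, skip_first: bool = False) -> int:
        convs = self.conv_layers[1:] if skip_first else self.conv_layers
        return sum(c.w.value.size for c in convs)


def build_patch_classifier(cfg: PatchClassifierConfig) -> PatchClassifier:
    return PatchClassifier(cfg)


# ---------------------------------------------------------------- training

def _dice_cancer(proba: np.ndarray, target: np.ndarray, cancer_idx: int = 0) -> float:
    """Cancer-vs-rest Dice of the argmax prediction (1.0 when both empty)."""
    pred = proba.argmax(axis=-1) == cancer_idx
    ref = target.argmax(axis=-1) == cancer_idx
    denom = pred.sum() + ref.sum()
    return 1.0 if denom == 0 else 2.0 * float((pred & ref).sum()) / float(denom)


def _evaluate(model, x, y, batch_size) -> dict:
    losses, dices, accs, n = [], [], [], x.shape[0]
    for i in range(0, n, batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        proba = softmax(logits)
        losses.append(loss * xb.shape[0])
        dices.append(_dice_cancer(proba, yb) * xb.shape[0])
        accs.append(float((proba.argmax(-1) == yb.argmax(-1)).mean()) * xb.shape[0])
    return {
        "loss": float(np.sum(losses) / n),
        "dice": float(np.sum(dices) / n),
        "accuracy": float(np.sum(accs) / n),
    }


def train(model, train_data, val_data, cfg: TrainConfig):
    """SGD training loop with early stopping and best-epoch weight restore.

    ``train_data``/``val_data`` are (x, y) tuples: x is N x H x W x 3 floats
    in [0, 1] (callers normalize uint8 by /255), y is one-hot -- per-pixel
    maps for segmentation models, per-patch vectors for the classifier.
    Returns (model, history); history holds per-epoch train/val loss and
    the monitored metric.  A NaN loss aborts with a diagnostic.
    """
    x_tr, y_tr = (np.asarray(a, dtype=np.float32) for a in train_data)
    x_va, y_va = (np.asarray(a, dtype=np.float32) for a in val_data)
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("train and validation sets must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    opt = _nn.SGD(model.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    history = {"train_loss": [], "val_loss": [], "val_dice": [], "val_accuracy": []}
    mode = "min" if cfg.monitor == "val_loss" else "max"
    best = np.inf if mode == "min" else -np.inf
    best_weights = _nn.get_weights(model.params())
    bad_epochs = 0

    n = x_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, step {i // cfg.batch_size}")
            opt.zero_grad()
            model.backward(dlogits)
            if cfg.clip_norm is not None:
                gnorm = np.sqrt(sum(float((p.grad**2).sum()) for p in opt.params))
                if gnorm > cfg.clip_norm:
                    scale = cfg.clip_norm / gnorm
                    for p in opt.params:
                        p.grad *= scale
            opt.step()
            ep_loss += loss * idx.size
        val = _evaluate(model, x_va, y_va, max(cfg.batch_size, 8))
        history["train_loss"].append(ep_loss / n)
        history["val_loss"].append(val["loss"])
        history["val_dice"].append(val["dice"])
        history["val_accuracy"].append(val["accuracy"])

        current = {"val_loss": val["loss"], "val_dice": val["dice"],
                   "val_accuracy": val["accuracy"]}[cfg.monitor]
        improved = current < best if mode == "min" else current > best
        if improved:
            best = current
            best_weights = _nn.get_weights(model.params())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    _nn.set_weights(model.params(), best_weights)
    return model, history
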