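"""Training-patch extraction from sparse annotations.

Patches are taken strictly inside annotated polygons (unannotated tissue
has no reference label and is never sampled), each patch gets a
full-frame single-class one-hot target, and rarer classes are balanced by
heavier augmentation rather than by discarding majority-class patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box
from shapely.prepared import prep

from .wsi_io import CLASSES, CLASS_INDEX, AnnotationSet, SlidePyramid

__all__ = [
    "PatchRecord",
    "AugmentationConfig",
    "extract_patches",
    "make_target",
    "augment",
    "plan_balanced_sampling",
    "load_patch",
]


@dataclass(frozen=True)
class PatchRecord:
    slide_id: str | None
    x: int  # patch center, level-0 px
    y: int
    size: int
    class_label: str
    augmentation_multiplicity: int = 1


@dataclass
class AugmentationConfig:
    """Photometric + geometric augmentation ranges.

    Fractional deltas for brightness/contrast/saturation, right-angle
    rotations plus mirroring, additive Gaussian noise (8-bit units) and
    Gaussian blur.  Defaults are standard histopathology ranges.
    """

    brightness: tuple[float, float] = (-0.2, 0.2)
    contrast: tuple[float, float] = (-0.2, 0.2)
    saturation: tuple[float, float] = (-0.2, 0.2)
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    mirror: bool = True
    noise_sigma: tuple[float, float] = (0.0, 10.0)
    blur_sigma: tuple[float, float] = (0.0, 1.5)
    multiplier_cap: int = 10

    def __post_init__(self):
        for name in ("brightness", "contrast", "saturation", "noise_sigma", "blur_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is not well-ordered")
        if self.multiplier_cap < 1:
            raise ValueError("multiplier_cap must be >= 1")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(brightness=(0, 0), contrast=(0, 0), saturation=(0, 0),
                   rotations=(0,), mirror=False, noise_sigma=(0, 0), blur_sigma=(0, 0))


def extract_patches(annotations: AnnotationSet, patch_size: int, stride: int | None = None,
                    mag_scale: float = 1.0, slide_id: str | None = None,
                    strict: bool = False) -> list[PatchRecord]:
    """Grid-enumerate patches whose footprint fits fully inside one polygon.

    ``mag_scale`` maps the patch edge at target magnification to level-0
    pixels (footprint edge = patch_size * mag_scale).  Default stride is
    half the footprint, which raises yield from sparse annotations.  The
    default containment test checks the four footprint corners plus the
    center against the polygon; ``strict`` switches to full geometric
    box-in-polygon containment.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    foot = int(round(patch_size * mag_scale))
    stride = stride if stride is not None else max(1, foot // 2)
    if stride < 1:
        raise ValueError("stride must be >= 1")

    records: list[PatchRecord] = []
    for region in annotations:
        poly = region.shapely
        prepared = prep(poly)
        minx, miny, maxx, maxy = poly.bounds
        x0 = int(math.ceil(minx))
        y0 = int(math.ceil(miny))
        for y in range(y0, int(math.floor(maxy)) - foot + 2, stride):
            for x in range(x0, int(math.floor(maxx)) - foot + 2, stride):
                if strict:
                    ok = prepared.covers(box(x, y, x + foot, y + foot))
                else:
                    pts = [(x, y), (x + foot, y), (x, y + foot), (x + foot, y + foot),
                           (x + foot / 2, y + foot / 2)]
                    ok = all(prepared.covers(Point(px, py)) for px, py in pts)
                if ok:
                    records.append(PatchRecord(
                        slide_id=slide_id, x=x + foot // 2, y=y + foot // 2,
                        size=patch_size, class_label=region.class_label))
    return records


def load_patch(slide: SlidePyramid, record: PatchRecord, mag_scale: float = 1.0) -> np.ndarray:
    """Read a record's pixels from level 0 (resized if mag_scale != 1)."""
    foot = int(round(record.size * mag_scale))
    x0, y0 = record.x - foot // 2, record.y - foot // 2
    img = slide.read_region(0, x0, y0, foot, foot)
    if foot != record.size:
        from skimage.transform import resize
        img = np.clip(np.rint(resize(img.astype(float), (record.size, record.size, 3),
                                     anti_aliasing=mag_scale > 1)), 0, 255).astype(np.uint8)
    return img


def make_target(record: PatchRecord | str, patch_size: int | None = None,
                n_classes: int = 5) -> np.ndarray:
    """Full-frame one-hot target map for a single-class patch.

    Accepts a PatchRecord (patch_size defaults to the record's size) or a
    bare class label with an explicit patch_size.
    """
    if isinstance(record, PatchRecord):
        class_label = record.class_label
        patch_size = patch_size if patch_size is not None else record.size
    else:
        class_label = record
    if patch_size is None:
        raise ValueError("patch_size required when passing a bare class label")
    if class_label not in CLASS_INDEX:
        raise ValueError(f"unknown class {class_label!r}")
    idx = CLASS_INDEX[class_label]
    if idx >= n_classes:
        raise ValueError("class index exceeds n_classes")
    t = np.zeros((patch_size, patch_size, n_classes), dtype=np.float32)
    t[..., idx] = 1.0
    return t


def augment(patch: np.ndarray, cfg: AugmentationConfig, rng) -> np.ndarray:
    """One random photometric+geometric augmentation draw.

    Parameters are sampled uniformly from the configured ranges; the output
    is a uint8 raster of the input shape (rotations are right-angle only).
    Deterministic given the rng state.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be H x W x 3 RGB")
    x = patch.astype(np.float64)

    b = rng.uniform(*cfg.brightness)
    c = rng.uniform(*cfg.contrast)
    s = rng.uniform(*cfg.saturation)
    rot = cfg.rotations[rng.integers(len(cfg.rotations))]
    do_mirror = cfg.mirror and rng.random() < 0.5
    noise = rng.uniform(*cfg.noise_sigma)
    blur = rng.uniform(*cfg.blur_sigma)

    if b:
        x = x * (1.0 + b)
    if c:
        x = (x - 128.0) * (1.0 + c) + 128.0
    if s:
        gray = x.mean(axis=-1, keepdims=True)
        x = gray + (x - gray) * (1.0 + s)
    if rot:
        x = np.rot90(x, k=rot // 90)
    if do_mirror:
        x = x[:, ::-1]
    if blur > 0:
        x = np.stack([gaussian_filter(x[..., ch], blur) for ch in range(3)], axis=-1)
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=x.shape)
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def plan_balanced_sampling(records: list[PatchRecord], cfg: AugmentationConfig,
                           classes=CLASSES) -> dict[str, int]:
    """Per-class augmentation multipliers evening out effective patch counts.

    multiplier(c) = ceil(n_max / n_c), capped at cfg.multiplier_cap; a
    configured class with zero records is reported with multiplier 0
    rather than raising (sparse cohorts routinely miss a class).
    """
    counts = {c: 0 for c in classes}
    for r in records:
        counts[r.class_label] = counts.get(r.class_label, 0) + 1
    present = {c: n for c, n in counts.items() if n > 0}
    if not present:
        raise ValueError("no patch records to balance")
    n_max = max(present.values())
    plan: dict[str, int] = {}
    for c in classes:
        if counts.get(c, 0) == 0:
            plan[c] = 0
        else:
            plan[c] = min(cfg.multiplier_cap, math.ceil(n_max / counts[c]))
    return plan
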