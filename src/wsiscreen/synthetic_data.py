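"""Synthetic multi-center slide cohorts.

Real prostate-biopsy cohorts are proprietary, so the package ships a
generator that reproduces the *statistical structure* the pipeline relies
on: near-white background, tissue regions drawn from the five annotation
classes (cancer, benign, other tissue type, high-grade-PIN-like mimicker,
other) with distinguishable procedural textures, sparse polygon
annotations covering only part of each region, ~25% cancer prevalence at
the slide level, and per-center "scanner styles" (hue/saturation/
brightness/contrast shifts, blur or sharpening, sensor noise).

Everything is a pure function of (spec, seed): per-slide seeds derive from
one master seed by splitmix64 hashing so cohorts are reproducible and
parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from .wsi_io import (
    CLASSES,
    AnnotationSet,
    RegionSpec,
    SlidePyramid,
    write_annotations,
    write_slide,
)

__all__ = [
    "SlideSpec",
    "CenterStyle",
    "TEXTURES",
    "splitmix64",
    "apply_center_style",
    "generate_slide",
    "cohort_specs",
    "generate_cohort",
]

BACKGROUND_LEVEL = 245
MIN_SIZE = 1024


def splitmix64(*values: int) -> int:
    """Hash integers into a well-mixed 63-bit seed (splitmix64 finalizer)."""
    z = 0x9E3779B97F4A7C15
    for v in values:
        z = (z + int(v)) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        z = z ^ (z >> 31)
    return z & 0x7FFFFFFFFFFFFFFF


@dataclass(frozen=True)
class CenterStyle:
    """Scanner/staining appearance of one center.

    hue_shift in degrees; the scales are unitless multipliers; blur_sigma
    in pixels, with negative values meaning an unsharp-mask amount;
    noise_sigma in 8-bit intensity units.  The all-default style is the
    identity and leaves images bit-identical.
    """

    style_id: str = "identity"
    hue_shift: float = 0.0
    saturation_scale: float = 1.0
    brightness_scale: float = 1.0
    contrast_scale: float = 1.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        for name in ("saturation_scale", "brightness_scale", "contrast_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.hue_shift % 360 == 0
            and self.saturation_scale == 1.0
            and self.brightness_scale == 1.0
            and self.contrast_scale == 1.0
            and self.blur_sigma == 0.0
            and self.noise_sigma == 0.0
        )


@dataclass(frozen=True)
class SlideSpec:
    slide_id: str
    width: int = 4096
    height: int = 4096
    mpp: float = 0.97
    label: str = "normal"  # cancer | normal
    center_style_id: str = "identity"
    seed: int = 0

    def __post_init__(self):
        if self.width < MIN_SIZE or self.height < MIN_SIZE:
            raise ValueError(f"slide must be at least {MIN_SIZE} px on a side")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.label not in ("cancer", "normal"):
            raise ValueError("label must be 'cancer' or 'normal'")


# Per-class procedural texture parameters: flat base color, blob color,
# blob correlation length (gaussian sigma), blob area fraction, pixel noise.
TEXTURES: dict[str, dict] = {
    "cancer": dict(base=(150, 90, 160), blob=(88, 40, 110), sigma=2.0, density=0.45, noise=6.0),
    "benign": dict(base=(232, 172, 200), blob=(200, 120, 160), sigma=6.0, density=0.25, noise=6.0),
    "other_tissue_type": dict(base=(170, 200, 232), blob=(118, 160, 212), sigma=4.0, density=0.30, noise=6.0),
    "hg_pin": dict(base=(192, 132, 192), blob=(150, 85, 152), sigma=4.0, density=0.35, noise=6.0),
    "other": dict(base=(202, 192, 170), blob=(160, 150, 128), sigma=5.0, density=0.30, noise=6.0),
}


# ------------------------------------------------------------ scanner style

def apply_center_style(image: np.ndarray, style: CenterStyle, rng=None) -> np.ndarray:
    """Render an RGB image in a center's scanner style.

    Fixed operation order: color (hue, saturation, brightness, contrast),
    then blur/sharpen, then additive noise.  The identity style returns
    the input unchanged (bit-identical copy).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3 RGB")
    if style.is_identity:
        return image.copy()

    x = image.astype(np.float64)
    if style.hue_shift % 360 != 0 or style.saturation_scale != 1.0:
        hsv = rgb2hsv(np.clip(x, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + style.hue_shift / 360.0) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * style.saturation_scale, 0.0, 1.0)
        x = hsv2rgb(hsv) * 255.0
    if style.brightness_scale != 1.0:
        x = x * style.brightness_scale
    if style.contrast_scale != 1.0:
        x = (x - 128.0) * style.contrast_scale + 128.0
    if style.blur_sigma > 0:
        x = np.stack([gaussian_filter(x[..., c], style.blur_sigma) for c in range(3)], axis=-1)
    elif style.blur_sigma < 0:  # unsharp mask
        smooth = np.stack([gaussian_filter(x[..., c], 1.0) for c in range(3)], axis=-1)
        x = x + (-style.blur_sigma) * (x - smooth)
    if style.noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        x = x + rng.normal(0.0, style.noise_sigma, size=x.shape)
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


# ------------------------------------------------------------ slide drawing

def _star_polygon(rng, cx, cy, radius, n_vertices=14, wobble=0.30) -> np.ndarray:
    """Simple star-convex polygon around (cx, cy); wobble < 1 keeps it simple."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * (1.0 + wobble * rng.uniform(-1, 1, n_vertices))
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])


def _render_texture(shape, params, rng) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), params["sigma"])
    cut = np.quantile(f, 1.0 - params["density"])
    blob = f > cut
    img = np.empty(shape + (3,), dtype=np.float64)
    img[...] = params["base"]
    img[blob] = params["blob"]
    img += rng.normal(0.0, params["noise"], size=img.shape)
    return img


def _shrink_polygon(poly: np.ndarray, area_fraction: float) -> np.ndarray:
    """Scale a star-convex polygon toward its centroid to the given area fraction."""
    c = poly.mean(axis=0)
    return c + (poly - c) * np.sqrt(area_fraction)


def generate_slide(spec: SlideSpec, style: CenterStyle, return_truth: bool = False):
    """Render one synthetic slide.

    Returns (SlidePyramid, AnnotationSet, label) -- plus the ground-truth
    class raster (int8, -1 = background) when ``return_truth`` is set.
    Output is a pure function of (spec, style); the base tissue layout
    depends only on spec.seed, so the same spec rendered under two styles
    shows the same tissue (the re-scanning scenario).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    scale = min(h, w) / 1024.0

    # class composition of one slide
    counts = {
        "benign": rng.integers(2, 4),
        "other_tissue_type": rng.integers(1, 3),
        "hg_pin": rng.integers(0, 2),
        "other": rng.integers(1, 3),
        "cancer": rng.integers(1, 3) if spec.label == "cancer" else 0,
    }

    placed: list[tuple[float, float, float]] = []
    regions: list[tuple[str, np.ndarray]] = []
    for cls in CLASSES:  # fixed order keeps RNG stream stable
        for _ in range(int(counts[cls])):
            for _attempt in range(60):
                radius = scale * rng.uniform(85, 150)
                margin = 1.4 * radius
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                if all((cx - px) ** 2 + (cy - py) ** 2 > (1.35 * (radius + pr)) ** 2
                       for px, py, pr in placed):
                    placed.append((cx, cy, radius))
                    regions.append((cls, _star_polygon(rng, cx, cy, radius)))
                    break

    img = np.full((h, w, 3), float(BACKGROUND_LEVEL))
    img += rng.normal(0.0, 2.0, size=img.shape)
    truth = np.full((h, w), -1, dtype=np.int8)
    for cls, poly in regions:
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        if rr.size == 0:
            continue
        y0, y1 = rr.min(), rr.max() + 1
        x0, x1 = cc.min(), cc.max() + 1
        tex = _render_texture((y1 - y0, x1 - x0), TEXTURES[cls], rng)
        img[rr, cc] = tex[rr - y0, cc - x0]
        truth[rr, cc] = CLASSES.index(cls)
    base = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # sparse annotations: a centroid-shrunk copy of a subset of regions
    ann_regions: list[RegionSpec] = []
    for i, (cls, poly) in enumerate(regions):
        annotate = rng.random() < 0.85
        frac = rng.uniform(0.30, 0.60)
        if cls == "cancer" and not any(r.class_label == "cancer" for r in ann_regions):
            annotate = True  # every cancer slide carries >= 1 cancer annotation
        if annotate:
            ann_regions.append(RegionSpec(_shrink_polygon(poly, frac), cls,
                                          name=f"{spec.slide_id}_r{i}"))
    annotations = AnnotationSet(regions=ann_regions, source_dialect=None)

    styled = apply_center_style(base, style,
                                rng=np.random.default_rng(splitmix64(spec.seed, 1)))
    level1 = np.clip(np.rint(resize(styled.astype(float), (h // 2, w // 2, 3),
                                    anti_aliasing=True)), 0, 255).astype(np.uint8)
    pyramid = SlidePyramid([styled, level1], mpp_x=spec.mpp, slide_id=spec.slide_id)

    if return_truth:
        return pyramid, annotations, spec.label, truth
    return pyramid, annotations, spec.label


# ---------------------------------------------------------------- cohorts

def cohort_specs(n: int, prevalence: float, styles: list[CenterStyle], seed: int,
                 size: int = 4096, mpp: float = 0.97,
                 style_assignment: str = "round_robin") -> list[tuple[SlideSpec, CenterStyle]]:
    """Slide specs for an n-slide cohort; labels are seeded Bernoulli draws.

    Style assignment is round-robin by default or contiguous per-center
    blocks with ``style_assignment='blocks'``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if not styles:
        raise ValueError("at least one center style required")
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < prevalence
    out = []
    for i in range(n):
        if style_assignment == "round_robin":
            style = styles[i % len(styles)]
        elif style_assignment == "blocks":
            style = styles[min(i * len(styles) // n, len(styles) - 1)]
        else:
            raise ValueError(f"unknown style_assignment {style_assignment!r}")
        spec = SlideSpec(
            slide_id=f"slide_{i:04d}",
            width=size, height=size, mpp=mpp,
            label="cancer" if labels[i] else "normal",
            center_style_id=style.style_id,
            seed=splitmix64(seed, 1000 + i),
        )
        out.append((spec, style))
    return out


def generate_cohort(n: int, prevalence: float, styles: list[CenterStyle], seed: int,
                    out_dir=None, size: int = 4096, mpp: float = 0.97,
                    style_assignment: str = "round_robin") -> pd.DataFrame:
    """Generate a cohort manifest; write slides + annotations when out_dir given.

    The manifest has one row per slide with columns slide_id, path,
    annotation_path, label, center_style_id (paths empty for in-memory use).
    """
    pairs = cohort_specs(n, prevalence, styles, seed, size=size, mpp=mpp,
                         style_assignment=style_assignment)
    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "slides").mkdir(parents=True, exist_ok=True)
        (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    for spec, style in pairs:
        slide_path = ann_path = ""
        if out_dir is not None:
            pyramid, annotations, _ = generate_slide(spec, style)
            slide_path = str(out_dir / "slides" / f"{spec.slide_id}.tif")
            ann_path = str(out_dir / "annotations" / f"{spec.slide_id}.xml")
            write_slide(pyramid, slide_path)
            write_annotations(annotations, ann_path, "asap_xml")
            write_annotations(annotations,
                              out_dir / "annotations" / f"{spec.slide_id}.geojson",
                              "geojson")
        rows.append(dict(slide_id=spec.slide_id, path=slide_path,
                         annotation_path=ann_path, label=spec.label,
                         center_style_id=spec.center_style_id))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
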