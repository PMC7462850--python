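"""Whole-slide likelihood maps and tumor-map derivation.

A trained model is applied to a slide tile-by-tile over the tissue mask;
tiles below the tissue-fraction cutoff are skipped and assigned a fixed
background distribution (all probability mass on the "other" class).  The
tumor probability map (TPM) is the cancer channel of the assembled map,
and the tumor area (TA) is the set of pixels where the cancer class beats
every other class strictly -- exact ties are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wsi_io import CLASSES, CLASS_INDEX, SlidePyramid, TissueMask

__all__ = ["LikelihoodMap", "TumorMap", "predict_slide", "derive_tumor_map"]

CANCER_IDX = CLASS_INDEX["cancer"]
BACKGROUND_IDX = CLASS_INDEX["other"]


@dataclass
class LikelihoodMap:
    probs: np.ndarray  # H x W x n_classes, per-pixel probabilities
    mpp: float
    slide_id: str | None = None

    def __post_init__(self):
        if self.probs.ndim != 3:
            raise ValueError("likelihood map must be H x W x C")


@dataclass
class TumorMap:
    tpm: np.ndarray  # H x W cancer-class probability
    ta: np.ndarray   # H x W bool, strict-argmax cancer region

    def __post_init__(self):
        if self.tpm.shape != self.ta.shape:
            raise ValueError("TPM/TA shape mismatch")


def _background_distribution(n_classes: int) -> np.ndarray:
    bg = np.zeros(n_classes, dtype=np.float32)
    bg[BACKGROUND_IDX] = 1.0
    return bg


def predict_slide(model, slide: SlidePyramid, tissue_mask: TissueMask,
                  patch_size: int, level: int = 0, batch_size: int = 32,
                  tissue_threshold: float = 0.05, overlap: bool = False) -> LikelihoodMap:
    """Tile the slide, classify tissue tiles, assemble the class-probability map.

    A tile is classified when at least ``tissue_threshold`` of its footprint
    is tissue.  Right/bottom remainder tiles are reflect-padded to the patch
    size and the prediction cropped back.  ``overlap`` adds a half-stride
    pass whose probabilities are averaged with the base grid (seam
    suppression); the default is the plain non-overlapping grid.

    Patch classifiers (models whose output is one vector per patch)
    broadcast their probability vector over the tile footprint.
    """
    arr = slide.level_array(level)
    h, w = arr.shape[:2]
    n_classes = len(CLASSES)
    if tissue_mask.level != level:
        raise ValueError("tissue mask level must match the analysis level")
    mask = tissue_mask.mask
    if mask.shape != (h, w):
        raise ValueError("tissue mask does not match slide level geometry")

    probs = np.zeros((h, w, n_classes), dtype=np.float32)
    probs[...] = _background_distribution(n_classes)
    weight = np.zeros((h, w, 1), dtype=np.float32)

    def _run_grid(offset: int):
        tiles, coords = [], []

        def _flush():
            if not tiles:
                return
            batch = np.stack(tiles).astype(np.float32) / 255.0
            out = model.predict_proba(batch)
            for t, (ty, tx, th, tw) in enumerate(coords):
                if out.ndim == 2:  # patch classifier: broadcast over footprint
                    tile_probs = np.broadcast_to(out[t], (patch_size, patch_size, n_classes))
                else:
                    tile_probs = out[t]
                sl = probs[ty : ty + th, tx : tx + tw]
                wv = weight[ty : ty + th, tx : tx + tw]
                add = tile_probs[:th, :tw]
                # running average over overlapping passes
                sl[...] = np.where(wv > 0, (sl * wv + add) / (wv + 1), add)
                wv += 1.0
            tiles.clear()
            coords.clear()

        ys = range(offset, h, patch_size)
        xs = range(offset, w, patch_size)
        for ty in ys:
            for tx in xs:
                th = min(patch_size, h - ty)
                tw = min(patch_size, w - tx)
                frac = mask[ty : ty + th, tx : tx + tw].mean()
                if frac < tissue_threshold:
                    continue
                tile = arr[ty : ty + th, tx : tx + tw]
                if th < patch_size or tw < patch_size:
                    tile = np.pad(tile, ((0, patch_size - th), (0, patch_size - tw), (0, 0)),
                                  mode="reflect")
                tiles.append(tile)
                coords.append((ty, tx, th, tw))
                if len(tiles) >= batch_size:
                    _flush()
        _flush()

    _run_grid(0)
    if overlap:
        _run_grid(patch_size // 2)

    return LikelihoodMap(probs=probs, mpp=slide.mpp_at(level), slide_id=slide.slide_id)


def derive_tumor_map(lmap: LikelihoodMap) -> TumorMap:
    """TPM = cancer channel; TA = pixels where cancer strictly wins the argmax."""
    p = lmap.probs
    tpm = p[..., CANCER_IDX].astype(np.float64)
    others = np.delete(p, CANCER_IDX, axis=-1)
    ta = tpm > others.max(axis=-1)
    return TumorMap(tpm=tpm, ta=ta)
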