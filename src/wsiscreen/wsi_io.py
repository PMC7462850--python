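"""Pyramidal slide I/O, polygon annotations and tissue masking.

Coordinate convention, used everywhere in the package: 0-based pixels,
top-left origin; region requests address (x, y) in level-0 coordinates
with (w, h) in pixels of the requested level; regions are half-open
[x, x+w) x [y, y+h).

Slides are tiled multi-page TIFFs (one page per pyramid level) with the
microns-per-pixel metadata carried in a JSON ImageDescription.  Two
annotation dialects are supported: ASAP-XML (class in the Annotation's
PartOfGroup attribute) and GeoJSON (class in properties.classification.name).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize

CLASSES = ("cancer", "benign", "other_tissue_type", "hg_pin", "other")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

__all__ = [
    "CLASSES",
    "CLASS_INDEX",
    "RegionSpec",
    "AnnotationSet",
    "SlidePyramid",
    "TissueMask",
    "read_slide",
    "write_slide",
    "read_region",
    "read_annotations",
    "write_annotations",
    "compute_tissue_mask",
]


@dataclass
class RegionSpec:
    """A labeled simple polygon in level-0 pixel coordinates."""

    polygon: np.ndarray  # (n, 2) array of (x, y) vertices, closed implicitly
    class_label: str
    name: str | None = None

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")
        if self.class_label not in CLASS_INDEX:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not self.shapely.is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def area(self) -> float:
        return self.shapely.area


@dataclass
class AnnotationSet:
    regions: list[RegionSpec] = field(default_factory=list)
    source_dialect: str | None = None  # asap_xml | geojson

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_class(self, class_label: str) -> list[RegionSpec]:
        return [r for r in self.regions if r.class_label == class_label]


class SlidePyramid:
    """In-memory multi-resolution image with physical-resolution metadata.

    ``levels`` holds (width, height, downsample) per level; downsamples
    increase from 1 at level 0.
    """

    def __init__(self, level_arrays: list[np.ndarray], mpp_x: float, mpp_y: float | None = None,
                 slide_id: str | None = None):
        if not level_arrays:
            raise ValueError("at least one pyramid level required")
        if mpp_x <= 0:
            raise ValueError("mpp must be positive")
        self._arrays = [np.asarray(a) for a in level_arrays]
        h0, w0 = self._arrays[0].shape[:2]
        self.levels = []
        prev_ds = 0.0
        for a in self._arrays:
            h, w = a.shape[:2]
            ds = w0 / w
            if ds <= prev_ds:
                raise ValueError("downsamples must increase monotonically")
            prev_ds = ds
            self.levels.append((w, h, ds))
        self.mpp_x = float(mpp_x)
        self.mpp_y = float(mpp_y if mpp_y is not None else mpp_x)
        self.slide_id = slide_id

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def dimensions(self) -> tuple[int, int]:
        return self.levels[0][:2]

    def level_array(self, level: int) -> np.ndarray:
        if not 0 <= level < self.n_levels:
            raise ValueError(f"invalid level {level}")
        return self._arrays[level]

    def read_region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        return read_region(self, level, x, y, w, h)

    def mpp_at(self, level: int) -> float:
        return self.mpp_x * self.levels[level][2]


def read_region(slide: SlidePyramid, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
    """Extract an h x w x 3 region; (x, y) in level-0 px, (w, h) at ``level``."""
    if w < 1 or h < 1:
        raise ValueError("region width and height must be >= 1")
    arr = slide.level_array(level)
    ds = slide.levels[level][2]
    xl = int(round(x / ds))
    yl = int(round(y / ds))
    lw, lh, _ = slide.levels[level]
    if xl < 0 or yl < 0 or xl + w > lw or yl + h > lh:
        raise ValueError("region out of bounds")
    return arr[yl : yl + h, xl : xl + w]


# ----------------------------------------------------------------- TIFF I/O

def write_slide(slide: SlidePyramid, path) -> None:
    """Write a tiled multi-page TIFF (one page per level) with mpp metadata."""
    path = Path(path)
    desc = json.dumps({"mpp_x": slide.mpp_x, "mpp_y": slide.mpp_y,
                       "slide_id": slide.slide_id, "n_levels": slide.n_levels})
    with tifffile.TiffWriter(path) as tw:
        for i in range(slide.n_levels):
            arr = slide.level_array(i)
            tw.write(arr, tile=(256, 256), photometric="rgb",
                     description=desc if i == 0 else None, compression=None)


def read_slide(path) -> SlidePyramid:
    with tifffile.TiffFile(path) as tf:
        arrays = [p.asarray() for p in tf.pages]
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    return SlidePyramid(
        arrays,
        mpp_x=float(meta.get("mpp_x", 1.0)),
        mpp_y=float(meta.get("mpp_y", meta.get("mpp_x", 1.0))),
        slide_id=meta.get("slide_id"),
    )


# -------------------------------------------------------------- annotations

def write_annotations(annotations: AnnotationSet, path, dialect: str) -> None:
    path = Path(path)
    if dialect == "asap_xml":
        root = ET.Element("ASAP_Annotations")
        anns = ET.SubElement(root, "Annotations")
        for i, r in enumerate(annotations):
            a = ET.SubElement(anns, "Annotation", Name=r.name or f"Annotation {i}",
                              Type="Polygon", PartOfGroup=r.class_label, Color="#F4FA58")
            coords = ET.SubElement(a, "Coordinates")
            for j, (x, y) in enumerate(r.polygon):
                ET.SubElement(coords, "Coordinate", Order=str(j), X=str(x), Y=str(y))
        groups = ET.SubElement(root, "AnnotationGroups")
        for c in sorted({r.class_label for r in annotations}):
            ET.SubElement(groups, "Group", Name=c, PartOfGroup="None", Color="#F4FA58")
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    elif dialect == "geojson":
        feats = []
        for r in annotations:
            ring = r.polygon.tolist()
            if ring[0] != ring[-1]:
                ring = ring + [ring[0]]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": {"name": r.class_label},
                               "name": r.name},
            })
        path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_annotations(path, dialect: str, class_map: dict[str, str] | None = None) -> AnnotationSet:
    """Parse polygon annotations; unknown class names raise unless mapped."""
    path = Path(path)
    class_map = class_map or {}

    def _label(name: str) -> str:
        name = class_map.get(name, name)
        if name not in CLASS_INDEX:
            raise ValueError(f"unknown annotation class {name!r}; supply a class_map")
        return name

    regions: list[RegionSpec] = []
    if dialect == "asap_xml":
        root = ET.parse(path).getroot()
        for a in root.iter("Annotation"):
            coords = sorted(
                ((int(c.get("Order")), float(c.get("X")), float(c.get("Y")))
                 for c in a.iter("Coordinate")),
                key=lambda t: t[0],
            )
            poly = np.array([(x, y) for _, x, y in coords])
            regions.append(RegionSpec(poly, _label(a.get("PartOfGroup")), name=a.get("Name")))
    elif dialect == "geojson":
        data = json.loads(path.read_text())
        for f in data.get("features", []):
            geom = f["geometry"]
            if geom["type"] != "Polygon":
                raise ValueError(f"unsupported geometry {geom['type']!r}")
            ring = np.asarray(geom["coordinates"][0], dtype=float)
            if len(ring) > 3 and np.allclose(ring[0], ring[-1]):
                ring = ring[:-1]
            name = f.get("properties", {}).get("classification", {}).get("name")
            regions.append(RegionSpec(ring, _label(name),
                                      name=f.get("properties", {}).get("name")))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return AnnotationSet(regions=regions, source_dialect=dialect)


# -------------------------------------------------------------- tissue mask

@dataclass
class TissueMask:
    mask: np.ndarray  # bool raster at ``level``
    level: int

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


def compute_tissue_mask(slide: SlidePyramid, level: int | None = None,
                        white_fraction: float = 0.9, min_size: int = 64) -> TissueMask:
    """Foreground detection: saturation Otsu OR'd with a brightness cutoff.

    The image is analyzed at <= 1024 px width (downsampled if needed),
    components smaller than ``min_size`` px are dropped and holes filled,
    then the mask is returned at the requested level's resolution.
    """
    if level is None:
        level = slide.n_levels - 1
    arr = np.asarray(slide.level_array(level), dtype=np.float64) / 255.0
    h, w = arr.shape[:2]
    scale = max(1.0, w / 1024.0)
    work = resize(arr, (int(round(h / scale)), int(round(w / scale))),
                  anti_aliasing=True) if scale > 1 else arr

    hsv = rgb2hsv(work)
    sat = hsv[..., 1]
    intensity = work.mean(axis=-1)
    not_white = intensity < white_fraction
    try:
        otsu = sat > threshold_otsu(sat)
    except ValueError:  # constant saturation
        otsu = np.zeros_like(sat, dtype=bool)
    mask = (otsu & not_white) | (intensity < 0.75)

    lab, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        mask = np.isin(lab, keep)
    mask = ndimage.binary_fill_holes(mask)

    if work.shape[:2] != (h, w):
        mask = resize(mask.astype(float), (h, w), order=0) > 0.5
    return TissueMask(mask=mask, level=level)
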