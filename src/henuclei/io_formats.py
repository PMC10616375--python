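"""Persistent artifacts: GeoJSON nucleus polygons, patch folders, label masks.

Detected nuclei are exported as an RFC 7946 FeatureCollection of Polygons in
the QuPath dialect (class name under ``properties.classification.name``),
which is how interactive pathology tools exchange annotations.  Polygon
coordinates live on the pixel-box lattice: a pixel (row r, column c) is the
unit square [c, c+1) x [r, r+1) with x = column and y = row, so the traced
boundary of a 10x10 pixel square has shoelace area exactly 100.  Exporting
polygons instead of masks keeps whole-slide outputs small.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box, shape as shapely_shape
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .synthetic import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusRecord",
    "PatchFolder",
    "instances_to_geojson",
    "geojson_to_instances",
    "write_patch_folder",
    "read_patch_folder",
    "write_label_mask",
    "read_label_mask",
]

_CLASS_ALIASES = {name: name for name in CLASS_NAMES}
_CLASS_ALIASES["non-neoplastic epithelial"] = "epithelial"


@dataclass
class NucleusRecord:
    """One detected nucleus: closed polygon, class, optional features."""

    id: int
    polygon: list[tuple[float, float]]  # first vertex repeated last
    class_name: str
    features: dict | None = None

    def __post_init__(self) -> None:
        if len(self.polygon) < 4:
            raise ValueError("polygon needs >= 4 vertices (closed triangle minimum)")
        if tuple(self.polygon[0]) != tuple(self.polygon[-1]):
            raise ValueError("polygon ring must be closed (first vertex repeated last)")
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")


@dataclass
class PatchFolder:
    """A folder of PNG patches named ``x{col}_y{row}.png``."""

    root: Path
    patches: list[tuple[np.ndarray, tuple[int, int]]] = dc_field(default_factory=list)


def _region_polygon(mask: np.ndarray, offset_rc: tuple[int, int]) -> Polygon:
    """Exact lattice polygon of a filled binary region.

    The region is decomposed into per-row run-length rectangles on the
    pixel-box lattice and unioned; for a connected region with holes filled
    this yields a single simple polygon whose shoelace area equals the pixel
    count.
    """
    r0, c0 = offset_rc
    rects = []
    for r in range(mask.shape[0]):
        row = mask[r]
        # run starts/stops within the row
        d = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        for s, e in zip(starts, stops):
            rects.append(box(c0 + s, r0 + r, c0 + e, r0 + r + 1))
    poly = unary_union(rects)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return orient(Polygon(poly.exterior), sign=1.0)


def instances_to_geojson(
    instances: np.ndarray,
    classes: dict[int, int] | dict[int, str],
    origin: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Trace every instance into a GeoJSON Feature.

    Parameters
    ----------
    instances : (H, W) label map (0 = background).
    classes : instance label -> class (index 1..5 or name).
    origin : (x, y) offset of this patch in the parent image; added to all
        coordinates.

    Returns
    -------
    A FeatureCollection dict; one Feature per instance with Polygon geometry
    (outer contour only, holes filled) and the class stored under
    ``properties.classification.name``.  Instances with fewer than 3 pixels
    are skipped with a logged warning.
    """
    instances = np.asarray(instances)
    ox, oy = origin
    features = []
    slices = ndimage.find_objects(instances)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        if lab not in classes:
            raise ValueError(f"instance {lab} has no class label")
        cval = classes[lab]
        cname = cval if isinstance(cval, str) else CLASS_NAMES[cval - 1]
        mask = instances[sl] == lab
        if int(mask.sum()) < 3:
            logger.warning("instance %d has < 3 pixels; skipped", lab)
            continue
        mask = ndimage.binary_fill_holes(mask)
        poly = _region_polygon(mask, (sl[0].start, sl[1].start))
        coords = [[float(x + ox), float(y + oy)] for x, y in poly.exterior.coords]
        features.append(
            {
                "type": "Feature",
                "id": int(lab),
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {"classification": {"name": cname}},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_instances(
    collection: dict,
    canvas_shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, dict[int, int]]:
    """Rasterize a FeatureCollection back to a label map + class dict.

    A pixel belongs to a polygon when its centre (c+0.5, r+0.5) lies inside;
    for lattice polygons produced by :func:`instances_to_geojson` this is the
    exact inverse.  Overlaps resolve later-feature-wins.  Class names are
    matched case-insensitively; "non-neoplastic epithelial" maps to
    epithelial.
    """
    h, w = canvas_shape
    ox, oy = origin
    labels = np.zeros((h, w), dtype=np.int32)
    classes: dict[int, int] = {}
    for i, feat in enumerate(collection.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(
                f"feature {i}: only Polygon geometries are supported, got {geom.get('type')!r}"
            )
        raw = (feat.get("properties", {}).get("classification", {}) or {}).get("name", "")
        cname = _CLASS_ALIASES.get(str(raw).strip().lower())
        if cname is None:
            raise ValueError(
                f"feature {i}: unknown class {raw!r}; accepted: "
                + ", ".join(sorted(set(_CLASS_ALIASES)))
            )
        poly = shapely_shape(geom)
        if not poly.is_valid:
            poly = poly.buffer(0)
        minx, miny, maxx, maxy = poly.bounds
        c_lo = max(int(np.floor(minx - ox)), 0)
        c_hi = min(int(np.ceil(maxx - ox)), w)
        r_lo = max(int(np.floor(miny - oy)), 0)
        r_hi = min(int(np.ceil(maxy - oy)), h)
        if c_hi <= c_lo or r_hi <= r_lo:
            continue
        cc, rr = np.meshgrid(np.arange(c_lo, c_hi), np.arange(r_lo, r_hi))
        inside = shapely.contains_xy(poly, cc.ravel() + 0.5 + ox, rr.ravel() + 0.5 + oy)
        lab = i + 1
        sub = labels[r_lo:r_hi, c_lo:c_hi].ravel()
        sub[inside] = lab
        labels[r_lo:r_hi, c_lo:c_hi] = sub.reshape(r_hi - r_lo, c_hi - c_lo)
        classes[lab] = CLASS_NAMES.index(cname) + 1
    # drop labels that were fully overwritten
    present = np.unique(labels)
    classes = {lab: ci for lab, ci in classes.items() if lab in present}
    return labels, classes


_PATCH_RE = re.compile(r"^x(\d+)_y(\d+)\.png$")


def write_patch_folder(
    patches: list[tuple[np.ndarray, tuple[int, int]]],
    root: str | Path,
) -> PatchFolder:
    """Write patches as lossless PNGs named ``x{col}_y{row}.png``.

    ``patches`` is a list of (image, (row, col)) with the origin in parent
    image pixels.  Colliding origins raise.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    seen: set[tuple[int, int]] = set()
    for img, (row, col) in patches:
        if (row, col) in seen:
            raise ValueError(f"duplicate patch origin (row={row}, col={col})")
        seen.add((row, col))
        iio.imwrite(root / f"x{col}_y{row}.png", np.asarray(img))
    return PatchFolder(root=root, patches=list(patches))


def read_patch_folder(root: str | Path) -> PatchFolder:
    """Read a patch folder back; inverse of :func:`write_patch_folder`."""
    root = Path(root)
    patches = []
    for p in sorted(root.iterdir()):
        m = _PATCH_RE.match(p.name)
        if not m:
            continue
        col, row = int(m.group(1)), int(m.group(2))
        patches.append((iio.imread(p), (row, col)))
    patches.sort(key=lambda t: t[1])
    return PatchFolder(root=root, patches=patches)


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Save an instance label map as 16-bit PNG (supports >255 nuclei)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.int32)
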