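"""Whole-image tiling, tissue detection, and patch filtering.

Stained slides are mostly empty glass; before segmentation a large image is
partitioned into fixed-size patches (default 1250 x 1250 px, the patch size
used throughout this pipeline) and patches without tissue or without signal
are discarded.  Tissue detection thresholds the HSV saturation channel with
Otsu's method — stained tissue is saturated, glass and glare are not — and
two patch filters are applied: minimum tissue fraction and minimum grayscale
standard deviation.  Both thresholds are deliberately simple and exposed as
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = ["TileGrid", "tile_image", "tissue_mask", "filter_patches", "extract_patch"]

DEFAULT_PATCH_SIZE = 1250
DEFAULT_MIN_TISSUE_FRACTION = 0.1
DEFAULT_MIN_STD = 5.0


@dataclass
class TileGrid:
    """A row-major grid of patch origins over an image.

    ``reasons`` holds, per origin, the names of the filters that rejected
    the patch; an empty tuple means the patch is kept.
    """

    image_shape: tuple[int, int]
    patch_size: int
    stride: int
    origins: list[tuple[int, int]]  # (row, col)
    reasons: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    @property
    def kept(self) -> list[tuple[int, int]]:
        return [o for o in self.origins if not self.reasons.get(o, ())]

    def patch_shape(self, origin: tuple[int, int]) -> tuple[int, int]:
        r, c = origin
        h, w = self.image_shape
        return min(self.patch_size, h - r), min(self.patch_size, w - c)


def tile_image(
    image: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int | None = None,
) -> TileGrid:
    """Partition an image into a grid of patch origins.

    Non-overlapping by default (stride = patch_size).  Right/bottom
    remainder patches are kept at reduced size, so the union of patch
    footprints equals the image footprint.  Ordering is row-major.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if stride is None:
        stride = patch_size
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    rows = list(range(0, h, stride)) if stride == patch_size else _covering(h, patch_size, stride)
    cols = list(range(0, w, stride)) if stride == patch_size else _covering(w, patch_size, stride)
    origins = [(r, c) for r in rows for c in cols]
    return TileGrid(image_shape=(h, w), patch_size=patch_size, stride=stride, origins=origins)


def _covering(extent: int, patch: int, stride: int) -> list[int]:
    """Origins along one axis for overlapping tiling covering the extent."""
    if extent <= patch:
        return [0]
    starts = list(range(0, extent - patch, stride))
    starts.append(extent - patch)
    return sorted(set(starts))


def extract_patch(image: np.ndarray, grid: TileGrid, origin: tuple[int, int]) -> np.ndarray:
    r, c = origin
    ph, pw = grid.patch_shape(origin)
    return image[r : r + ph, c : c + pw]


def tissue_mask(image: np.ndarray, min_object_px: int = 16) -> np.ndarray:
    """Binary tissue mask of an 8-bit RGB image.

    Otsu threshold on the HSV saturation channel, then removal of small
    connected specks.  White/near-gray background has near-zero saturation;
    stained tissue does not.
    """
    image = np.asarray(image)
    sat = rgb2hsv(image)[..., 1]
    if np.ptp(sat) < 1e-6:
        return np.zeros(sat.shape, dtype=bool)
    mask = sat > threshold_otsu(sat)
    # drop connected specks strictly smaller than min_object_px
    return remove_small_objects(mask, max_size=min_object_px - 1)


def filter_patches(
    grid: TileGrid,
    image: np.ndarray,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
    min_std: float = DEFAULT_MIN_STD,
) -> TileGrid:
    """Flag uninformative patches.

    A patch is kept iff its tissue fraction is >= ``min_tissue_fraction``
    AND its grayscale standard deviation (8-bit units) is >= ``min_std``.
    Each rejection records which filter(s) fired; filtering is monotone in
    both thresholds.
    """
    image = np.asarray(image)
    mask = tissue_mask(image)
    gray = rgb2gray(image) * 255.0
    reasons: dict[tuple[int, int], tuple[str, ...]] = {}
    for origin in grid.origins:
        r, c = origin
        ph, pw = grid.patch_shape(origin)
        fired = []
        if mask[r : r + ph, c : c + pw].mean() < min_tissue_fraction:
            fired.append("tissue_fraction")
        if gray[r : r + ph, c : c + pw].std() < min_std:
            fired.append("low_std")
        reasons[origin] = tuple(fired)
    return TileGrid(
        image_shape=grid.image_shape,
        patch_size=grid.patch_size,
        stride=grid.stride,
        origins=list(grid.origins),
        reasons=reasons,
    )
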