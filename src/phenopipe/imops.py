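"""Core segmentation operators.

A raw plant photograph (uniform background, single plant) is reduced to a
clean foreground crop by a four-stage pipeline:

1. **Background removal** — :func:`crop` to a region of interest, then
   :func:`color_filter` with a per-pixel predicate (e.g. ``g > b`` for green
   plants on blue/white backgrounds), which blackens failing pixels.
2. **Noise reduction** — :func:`contour_chop` deletes small connected
   components; :func:`morphological_open` is an alternative that erodes and
   re-dilates the foreground support.
3. **Cropping** — :func:`contour_cut` tightens the frame to the bounding box
   of the large components so height/width are measured on the plant alone.
4. **Binary conversion** — :func:`to_binary`; a pixel is foreground iff any
   channel is nonzero, which is exact because every operator here fills
   removed pixels with (0, 0, 0).

Conventions: images are (H, W, 3) uint8 arrays in red, green, blue order;
coordinates are 0-based row-major; ROIs are half-open ``[ystart, yend,
xstart, xend]``; connectivity is 8-connected (thin tillers and leaf tips
touch diagonally); a contour's area is its pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import ArgumentError, BoundsError, EmptyPlantError
from .filters import FilterExpression, parse_filter

__all__ = [
    "ROI",
    "Contour",
    "as_image",
    "crop",
    "color_filter",
    "to_binary",
    "find_contours",
    "contour_chop",
    "morphological_open",
    "contour_cut",
]

#: 8-connectivity structuring element shared by all component labelling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region ``[ystart, yend) x [xstart, xend)``, 0-based."""

    ystart: int
    yend: int
    xstart: int
    xend: int

    def validate(self, height: int, width: int) -> None:
        if self.ystart >= self.yend:
            raise BoundsError(f"empty ROI: ystart={self.ystart} >= yend={self.yend}")
        if self.xstart >= self.xend:
            raise BoundsError(f"empty ROI: xstart={self.xstart} >= xend={self.xend}")
        if self.ystart < 0:
            raise BoundsError(f"ystart={self.ystart} < 0")
        if self.xstart < 0:
            raise BoundsError(f"xstart={self.xstart} < 0")
        if self.yend > height:
            raise BoundsError(f"yend={self.yend} > image height {height}")
        if self.xend > width:
            raise BoundsError(f"xend={self.xend} > image width {width}")

    @classmethod
    def coerce(cls, roi: Union["ROI", Sequence[int]]) -> "ROI":
        if isinstance(roi, ROI):
            return roi
        ys, ye, xs, xe = (int(v) for v in roi)
        return cls(ys, ye, xs, xe)

    def as_slices(self) -> tuple[slice, slice]:
        return slice(self.ystart, self.yend), slice(self.xstart, self.xend)

    def to_list(self) -> list[int]:
        return [self.ystart, self.yend, self.xstart, self.xend]


@dataclass(frozen=True)
class Contour:
    """One 8-connected foreground component; area is its pixel count."""

    pixels: frozenset  # of (row, col)
    area: int

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return min(rows), max(rows), min(cols), max(cols)


def as_image(image: np.ndarray) -> np.ndarray:
    """Validate and normalise an array to (H, W, 3) uint8 RGB."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ArgumentError(f"expected (H, W, 3) image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ArgumentError(f"degenerate image shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ArgumentError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def crop(image: np.ndarray, roi: Union[ROI, Sequence[int]]) -> np.ndarray:
    """Extract the ROI as a new image; pixel (i, j) of the result is input
    pixel (ystart + i, xstart + j)."""
    img = as_image(image)
    r = ROI.coerce(roi)
    r.validate(*img.shape[:2])
    ys, xs = r.as_slices()
    return img[ys, xs].copy()


def color_filter(
    image: np.ndarray,
    expr: Union[str, FilterExpression],
    roi: Optional[Union[ROI, Sequence[int]]] = None,
) -> np.ndarray:
    """Blacken every pixel (inside ``roi``, or everywhere) that fails ``expr``.

    Pixels satisfying the predicate, and all pixels outside the ROI, are
    returned unchanged.  Because the fill color (0, 0, 0) itself fails any
    strict channel comparison such as ``g > b``, the filter is idempotent.
    """
    img = as_image(image).copy()
    predicate = parse_filter(expr)
    if roi is None:
        region = img
    else:
        r = ROI.coerce(roi)
        r.validate(*img.shape[:2])
        region = img[r.as_slices()]
    keep = predicate.evaluate(region)
    region[~keep] = 0
    return img


def to_binary(image: np.ndarray) -> np.ndarray:
    """Boolean foreground mask: True wherever any channel is nonzero."""
    img = as_image(image)
    return img.any(axis=2)


def find_contours(mask: np.ndarray) -> list[Contour]:
    """Connected components of the foreground under 8-connectivity.

    Components are returned sorted by their minimum (row, col) pixel so the
    ordering is deterministic; they are disjoint and their union is exactly
    the foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    contours = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        pixels = frozenset(zip(rows.tolist(), cols.tolist()))
        contours.append(Contour(pixels=pixels, area=len(pixels)))
    contours.sort(key=lambda c: min(c.pixels))
    return contours


def _label(image: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    mask = image.any(axis=2)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n:
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    else:
        areas = np.zeros(0, dtype=int)
    return labels, n, areas


def contour_chop(image: np.ndarray, min_area: int) -> np.ndarray:
    """Remove (blacken) every foreground component with area < ``min_area``.

    Components of area >= ``min_area`` are untouched; ``min_area = 0`` is the
    identity.  Removal is monotone in the threshold.
    """
    if min_area < 0:
        raise ArgumentError(f"min_area must be >= 0, got {min_area}")
    img = as_image(image).copy()
    labels, n, areas = _label(img)
    if n == 0:
        return img
    small = np.flatnonzero(areas < min_area) + 1
    if small.size:
        img[np.isin(labels, small)] = 0
    return img


def morphological_open(image: np.ndarray, kernel: int = 3, iterations: int = 1) -> np.ndarray:
    """Morphological opening of the foreground support.

    Erodes the binary support ``iterations`` times with a ``kernel`` x
    ``kernel`` square structuring element, then dilates the same number of
    times; pixels whose support is removed are blackened, surviving pixels
    keep their original color.  Outside the image counts as background.
    The output foreground is always a subset of the input foreground, and
    the operation is idempotent.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ArgumentError(f"kernel must be odd and >= 1, got {kernel}")
    if iterations < 1:
        raise ArgumentError(f"iterations must be >= 1, got {iterations}")
    img = as_image(image).copy()
    support = img.any(axis=2)
    structure = np.ones((kernel, kernel), dtype=bool)
    opened = ndimage.binary_opening(
        support, structure=structure, iterations=iterations, border_value=0
    )
    img[~opened] = 0
    return img


def contour_cut(
    image: np.ndarray, min_area: int, padding: int = 0
) -> tuple[np.ndarray, ROI]:
    """Crop to the bounding box of all components with area > ``min_area``.

    The box is expanded by ``padding`` pixels on each side (clamped to the
    image).  This is pure cropping: small components that happen to fall
    inside the box survive.  Returns the crop and the ROI actually used.

    Raises :class:`EmptyPlantError` (carrying the observed component areas)
    when no component exceeds the threshold.
    """
    if min_area < 0:
        raise ArgumentError(f"min_area must be >= 0, got {min_area}")
    if padding < 0:
        raise ArgumentError(f"padding must be >= 0, got {padding}")
    img = as_image(image)
    labels, n, areas = _label(img)
    keep = np.flatnonzero(areas > min_area) + 1
    if keep.size == 0:
        raise EmptyPlantError(
            f"no foreground component larger than {min_area} pixels",
            sorted(areas.tolist(), reverse=True),
        )
    selected = np.isin(labels, keep)
    rows, cols = np.nonzero(selected)
    h, w = img.shape[:2]
    roi = ROI(
        max(int(rows.min()) - padding, 0),
        min(int(rows.max()) + 1 + padding, h),
        max(int(cols.min()) - padding, 0),
        min(int(cols.max()) + 1 + padding, w),
    )
    return crop(img, roi), roi
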