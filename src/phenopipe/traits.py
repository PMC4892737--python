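"""Digital trait extraction from segmented plant images.

All shape descriptors operate on a boolean foreground mask.  Moments are
binary (weight 1 per foreground pixel) and computed in exact integer
arithmetic: ``M_ij = sum over foreground pixels of x**i * y**j`` with x the
column and y the row, so ``M00`` is the projected area and
``(M10/M00, M01/M00)`` the center of mass.

The convex-hull descriptors use a discrete definition — the hull area is
the number of *pixel centers* inside or on the convex hull of the
foreground pixel centers — which keeps the density ratio exactly 1 for any
filled convex shape and makes every value reproducible against a
brute-force lattice test.

:func:`composite_traits` assembles the per-plant catalog (heights, widths,
areas, projected shoot area, hull/density/growth-habit ratios, per-view raw
moments) from the three standard camera views: two side views 90 degrees
apart plus one top view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ArgumentError, EmptyMaskError, MissingViewError

__all__ = [
    "MomentSet",
    "ColorHistogram",
    "raw_moments",
    "center_of_mass",
    "dimensions",
    "pixel_area",
    "projected_shoot_area",
    "convex_hull",
    "hull_lattice_area",
    "hull_perimeter",
    "convex_hull_metrics",
    "color_histogram",
    "composite_traits",
    "TRAIT_FORMULAS",
]

MAX_ORDER = 3


@dataclass(frozen=True)
class MomentSet:
    """Raw binary-image moments up to order (3, 3), exact integers."""

    m: tuple  # m[i][j] = M_ij

    def __getitem__(self, ij: tuple[int, int]) -> int:
        return self.m[ij[0]][ij[1]]

    @property
    def area(self) -> int:
        return self.m[0][0]

    def as_dict(self) -> dict[str, int]:
        return {
            f"M{i}{j}": self.m[i][j]
            for i in range(MAX_ORDER + 1)
            for j in range(MAX_ORDER + 1)
        }


def raw_moments(mask: np.ndarray, max_order: int = MAX_ORDER) -> MomentSet:
    """Exact raw moments of a binary mask up to ``max_order`` in each index.

    An empty mask yields all-zero moments.  Arithmetic is exact: coordinate
    powers are accumulated as Python integers when 64-bit overflow is
    possible.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n = rows.size
    # x^i y^j <= d^(2*max_order); guard the summation against int64 overflow
    d = max(mask.shape) if n else 1
    exact = n > 0 and n * float(d) ** (2 * max_order) > 2**62
    if exact:
        rows = rows.astype(object)
        cols = cols.astype(object)
    else:
        rows = rows.astype(np.int64)
        cols = cols.astype(np.int64)
    m = []
    for i in range(max_order + 1):
        xi = cols**i
        row_m = []
        for j in range(max_order + 1):
            row_m.append(int(np.sum(xi * rows**j)) if n else 0)
        m.append(tuple(row_m))
    return MomentSet(m=tuple(m))


def center_of_mass(m: MomentSet) -> tuple[float, float]:
    """Centroid ``(x̄, ȳ) = (M10/M00, M01/M00)`` in (column, row) order."""
    if m.area == 0:
        raise EmptyMaskError("centroid undefined for an empty mask")
    return m[1, 0] / m.area, m[0, 1] / m.area


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("empty mask has no bounding box")
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def dimensions(mask: np.ndarray) -> tuple[int, int]:
    """(height, width) of the foreground bounding box, inclusive of both ends."""
    rmin, rmax, cmin, cmax = _bbox(np.asarray(mask, dtype=bool))
    return rmax - rmin + 1, cmax - cmin + 1


def pixel_area(mask: np.ndarray) -> int:
    """Foreground pixel count; identical to ``raw_moments(mask).area``."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def projected_shoot_area(area_sv0: int, area_sv90: int) -> int:
    """Projected shoot area: the sum of plant pixels over the two side views.

    A digital proxy for shoot biomass; the views are summed, never averaged.
    """
    if area_sv0 < 0 or area_sv90 < 0:
        raise ArgumentError("pixel areas must be non-negative")
    return int(area_sv0) + int(area_sv90)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of integer lattice points by Andrew's monotone chain.

    Returns hull vertices in counter-clockwise order in (x, y) coordinates
    with collinear boundary points removed; exact integer arithmetic.
    Degenerate inputs (a single point, a collinear set) return the 1 or 2
    extreme points.
    """
    pts = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    if len(pts) <= 2:
        return pts
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def cross(o, a, b) -> int:
        return int(a[0] - o[0]) * int(b[1] - o[1]) - int(a[1] - o[1]) * int(b[0] - o[0])

    def half(seq):
        chain: list = []
        for p in seq:
            while len(chain) >= 2 and cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 2:  # all points collinear collapse to the extremes
        return np.array([pts[0], pts[-1]], dtype=np.int64)
    return np.array(hull, dtype=np.int64)


def hull_lattice_area(hull: np.ndarray) -> int:
    """Count pixel centers of the grid inside or on the hull polygon, exactly.

    For a CCW hull every interior-or-boundary point has a non-negative cross
    product against every directed edge; integer arithmetic makes boundary
    membership exact.  Degenerate hulls (point/segment) are handled as such.
    """
    hull = np.asarray(hull, dtype=np.int64)
    if len(hull) == 0:
        return 0
    xmin, ymin = hull.min(axis=0)
    xmax, ymax = hull.max(axis=0)
    xs = np.arange(xmin, xmax + 1, dtype=np.int64)
    ys = np.arange(ymin, ymax + 1, dtype=np.int64)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    if len(hull) == 1:
        return 1
    inside = np.ones(gx.shape, dtype=bool)
    if len(hull) == 2:
        a, b = hull
        cross = (b[0] - a[0]) * (gy - a[1]) - (b[1] - a[1]) * (gx - a[0])
        return int(np.count_nonzero(cross == 0))
    for k in range(len(hull)):
        a = hull[k]
        b = hull[(k + 1) % len(hull)]
        cross = (b[0] - a[0]) * (gy - a[1]) - (b[1] - a[1]) * (gx - a[0])
        inside &= cross >= 0
    return int(np.count_nonzero(inside))


def hull_perimeter(hull: np.ndarray) -> float:
    """Euclidean perimeter of the hull polygon (0 for a point, 2·length for a segment)."""
    hull = np.asarray(hull, dtype=np.float64)
    if len(hull) < 2:
        return 0.0
    if len(hull) == 2:
        return 2.0 * float(np.hypot(*(hull[1] - hull[0])))
    diffs = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def convex_hull_metrics(mask: np.ndarray) -> tuple[int, float]:
    """(hull_area, density) of a nonempty mask.

    hull_area counts pixel centers inside or on the convex hull of the
    foreground pixel centers; density = pixel_area / hull_area lies in
    (0, 1] and equals 1 exactly for filled convex shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("convex hull undefined for an empty mask")
    hull = convex_hull(np.column_stack([cols, rows]))
    area = hull_lattice_area(hull)
    return area, rows.size / area


@dataclass(frozen=True)
class ColorHistogram:
    """Per-channel histogram over foreground pixels with fixed-width bins."""

    bins_per_channel: int
    counts: np.ndarray  # (3, bins) int64
    proportions: Optional[np.ndarray]  # None when the mask is empty

    @property
    def empty(self) -> bool:
        return self.proportions is None


def color_histogram(image: np.ndarray, mask: np.ndarray, bins: int = 8) -> ColorHistogram:
    """Histogram the three channels over foreground pixels only.

    ``bins`` must divide 256 so every bin spans ``256 // bins`` intensity
    levels exactly.  Counts per channel sum to the foreground pixel count;
    proportions are flagged undefined (None) on an empty mask.
    """
    if bins <= 0 or 256 % bins != 0:
        raise ArgumentError(f"bins must be a positive divisor of 256, got {bins}")
    img = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise ArgumentError(
            f"image shape {img.shape[:2]} does not match mask shape {mask.shape}"
        )
    width = 256 // bins
    fg = img[mask]  # (n, 3)
    counts = np.zeros((3, bins), dtype=np.int64)
    for c in range(3):
        counts[c] = np.bincount(fg[:, c] // width, minlength=bins)
    n = fg.shape[0]
    proportions = counts / n if n else None
    return ColorHistogram(bins_per_channel=bins, counts=counts, proportions=proportions)


# ---------------------------------------------------------------------------
# Composite per-plant trait catalog
# ---------------------------------------------------------------------------

REQUIRED_VIEWS = ("sv0", "sv90", "tv")

#: Human-auditable formula registry: trait name -> description.  The actual
#: computation lives in :func:`composite_traits`; this mapping is the
#: documented catalog and the single source of trait names.
TRAIT_FORMULAS: dict[str, str] = {
    "Height_SV": "foreground bounding-box height of the first side view (pixels)",
    "Width_SV": "foreground bounding-box width of the first side view (pixels)",
    "CA_SV": "cropped area: foreground pixel count of the first side view",
    "Area_TV": "foreground pixel count of the top view",
    "PSA": "projected shoot area: CA of side view 0 + CA of side view 90",
    "CH_SV": "convex-hull lattice area of the first side view (pixels)",
    "CH_TV": "convex-hull lattice area of the top view (pixels)",
    "Den1_SV": "CA_SV / CH_SV (hull density, side view)",
    "Den1_TV": "Area_TV / CH_TV (hull density, top view)",
    "Den2_SV": "CA_SV / (Height_SV * Width_SV) (bounding-box density, side view)",
    "Den2_TV": "Area_TV / (bbox height * bbox width) (bounding-box density, top view)",
    "Den3_SV": "4*pi*CA_SV / hull_perimeter_SV**2 (hull-perimeter compactness)",
    "Den3_TV": "4*pi*Area_TV / hull_perimeter_TV**2 (hull-perimeter compactness)",
    "GH1": "Width_SV / Height_SV (erect vs spreading growth habit)",
    "GH2": "(centroid row within bbox + 1) / Height_SV (relative centroid height)",
    "GH3": "sqrt(minor/major eigenvalue ratio of side-view central moments)",
    "GH4": "eccentricity sqrt(1 - minor/major) of top-view central moments",
}


def _axis_ratio(mask: np.ndarray) -> float:
    """Minor/major eigenvalue ratio of the binary second central moments."""
    rows, cols = np.nonzero(mask)
    n = rows.size
    x = cols - cols.mean()
    y = rows - rows.mean()
    cov = np.array([[x @ x, x @ y], [x @ y, y @ y]]) / n
    ev = np.linalg.eigvalsh(cov)
    if ev[1] <= 0:
        return 1.0  # single pixel or perfectly degenerate: treat as isotropic
    return max(ev[0], 0.0) / ev[1]


def composite_traits(views: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Assemble the full per-plant trait catalog from the three camera views.

    ``views`` maps view names (``sv0``, ``sv90``, ``tv``) to boolean
    foreground masks.  Returns the named traits of :data:`TRAIT_FORMULAS`
    plus the 16 raw moments ``M00..M33`` per view (suffixed ``_SV0``,
    ``_SV90``, ``_TV``).
    """
    missing = [v for v in REQUIRED_VIEWS if v not in views]
    if missing:
        raise MissingViewError(missing)
    masks = {v: np.asarray(views[v], dtype=bool) for v in REQUIRED_VIEWS}
    for name, m in masks.items():
        if not m.any():
            raise EmptyMaskError(f"view {name!r} has an empty foreground mask")

    sv, sv90, tv = masks["sv0"], masks["sv90"], masks["tv"]
    out: dict[str, float] = {}

    h_sv, w_sv = dimensions(sv)
    h_tv, w_tv = dimensions(tv)
    ca_sv = pixel_area(sv)
    ca_sv90 = pixel_area(sv90)
    area_tv = pixel_area(tv)
    ch_sv, den1_sv = convex_hull_metrics(sv)
    ch_tv, den1_tv = convex_hull_metrics(tv)

    out["Height_SV"] = float(h_sv)
    out["Width_SV"] = float(w_sv)
    out["CA_SV"] = float(ca_sv)
    out["Area_TV"] = float(area_tv)
    out["PSA"] = float(projected_shoot_area(ca_sv, ca_sv90))
    out["CH_SV"] = float(ch_sv)
    out["CH_TV"] = float(ch_tv)
    out["Den1_SV"] = den1_sv
    out["Den1_TV"] = den1_tv
    out["Den2_SV"] = ca_sv / (h_sv * w_sv)
    out["Den2_TV"] = area_tv / (h_tv * w_tv)

    rows_sv, cols_sv = np.nonzero(sv)
    per_sv = hull_perimeter(convex_hull(np.column_stack([cols_sv, rows_sv])))
    rows_tv, cols_tv = np.nonzero(tv)
    per_tv = hull_perimeter(convex_hull(np.column_stack([cols_tv, rows_tv])))
    out["Den3_SV"] = 4 * math.pi * ca_sv / per_sv**2 if per_sv > 0 else 1.0
    out["Den3_TV"] = 4 * math.pi * area_tv / per_tv**2 if per_tv > 0 else 1.0

    out["GH1"] = w_sv / h_sv
    rmin_sv = _bbox(sv)[0]
    centroid_row = float(np.nonzero(sv)[0].mean())
    out["GH2"] = (centroid_row - rmin_sv + 1.0) / h_sv
    out["GH3"] = math.sqrt(_axis_ratio(sv))
    ratio_tv = _axis_ratio(tv)
    out["GH4"] = math.sqrt(max(1.0 - ratio_tv, 0.0))

    for view, suffix in (("sv0", "_SV0"), ("sv90", "_SV90"), ("tv", "_TV")):
        for name, value in raw_moments(masks[view]).as_dict().items():
            out[name + suffix] = float(value)
    return out
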