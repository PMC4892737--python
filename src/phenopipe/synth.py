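"""Synthetic plant-image fixtures with exact ground truth.

Controlled-environment phenotyping images have a simple structure: a single
green plant in front of a uniform background (white, blue or black) that
differs strongly from it in color, a pot or support band near the bottom,
and occasional small debris.  This module renders deterministic plant-like
images with exactly known foreground pixel sets, directory trees shaped
like an automated imaging platform's output, and planted-group trait
tables — so segmentation, trait extraction, crawling, workflow execution
and clustering are all testable without any external dataset.

The plant is a vertical stem plus straight leaves, rasterised as a boolean
mask first; ground truth (pixel count, bounding box, raw moments, hull
area, color histogram) is computed from that exact mask before
compositing.  Debris defaults to colors that *fail* the canonical
``g > b`` foreground predicate, so the plain background-removal stage
cleans it; ``hard_noise=True`` makes green-like debris that only
connected-component area filtering can remove, exercising the noise
reduction stage separately.  All randomness flows from the explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, line

from .errors import ArgumentError, PhenopipeError

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "generate_plant_image",
    "generate_tree",
    "generate_trait_table",
    "TREE_PATTERN",
]

#: Path pattern matching the trees written by :func:`generate_tree`.
TREE_PATTERN = ["{id}_{date}", "{imtype}", "{angle}.png"]

BACKGROUND_BLUE = (70, 90, 200)
BACKGROUND_WHITE = (255, 255, 255)
POT_COLOR = (130, 135, 190)  # fails g > b
SOFT_DEBRIS_COLOR = (120, 125, 185)  # fails g > b: removed by the color filter
HARD_DEBRIS_COLOR = (90, 160, 70)  # green-like: survives g > b


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one rendered plant image.

    Defaults emulate a side view of a young cereal plant on a blue
    background: canvas 200 x 200, stem 60–120 px tall and 3 px thick, 3–7
    leaves, a 12-row pot band, and 3 small debris blobs.
    """

    seed: int = 0
    canvas: tuple[int, int] = (200, 200)
    stem_base: Optional[tuple[int, int]] = None  # (row, col); default bottom centre
    stem_height: int = 90
    stem_thickness: int = 3
    n_leaves: int = 5
    leaf_length: tuple[int, int] = (15, 45)
    background: tuple[int, int, int] = BACKGROUND_BLUE
    pot_band_rows: int = 12
    n_debris: int = 3
    debris_radius: tuple[int, int] = (1, 3)
    hard_noise: bool = False
    top_view: bool = False


@dataclass
class GroundTruth:
    """Exact foreground truth computed from the rasterised plant mask."""

    mask: np.ndarray  # (H, W) bool
    count: int
    bbox: tuple[int, int, int, int]  # rmin, rmax, cmin, cmax (inclusive)
    moments: dict[str, int]  # M00..M33
    hull_area: int
    histogram: np.ndarray  # (3, 8) foreground color counts
    debris_areas: list[int]  # pixel count of each debris component

    @property
    def largest_debris(self) -> int:
        return max(self.debris_areas, default=0)


def _gt_moments(mask: np.ndarray, max_order: int = 3) -> dict[str, int]:
    """Raw moments by direct coordinate-power summation (int64 is ample at
    fixture scale)."""
    rows, cols = np.nonzero(mask)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    return {
        f"M{i}{j}": int(np.sum(cols**i * rows**j))
        for i in range(max_order + 1)
        for j in range(max_order + 1)
    }


def _draw_side_plant(spec: PlantSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.canvas
    mask = np.zeros((h, w), dtype=bool)
    base_row, base_col = spec.stem_base or (h - spec.pot_band_rows - 1, w // 2)
    top_row = base_row - spec.stem_height + 1
    half = spec.stem_thickness // 2
    if top_row < 0 or base_row >= h or base_col - half < 0 or base_col + half >= w:
        raise ArgumentError(
            f"plant exceeds canvas: stem rows [{top_row}, {base_row}], "
            f"cols [{base_col - half}, {base_col + half}] vs canvas {spec.canvas}"
        )
    mask[top_row : base_row + 1, base_col - half : base_col - half + spec.stem_thickness] = True
    for _ in range(spec.n_leaves):
        start_row = int(rng.integers(top_row, base_row - 5)) if base_row - 5 > top_row else top_row
        length = int(rng.integers(*spec.leaf_length))
        direction = int(rng.choice([-1, 1]))
        rise = int(rng.integers(length // 3, length + 1))
        end_row = max(start_row - rise, 0)
        end_col = int(np.clip(base_col + direction * length, 0, w - 1))
        rr, cc = line(start_row, base_col, end_row, end_col)
        mask[rr, cc] = True
        if length > 25:  # thicken long leaves by one extra row
            rr2 = np.clip(rr + 1, 0, h - 1)
            mask[rr2, cc] = True
    return mask


def _draw_top_plant(spec: PlantSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.canvas
    mask = np.zeros((h, w), dtype=bool)
    centre = (h // 2, w // 2)
    n_arms = max(spec.n_leaves, 3)
    radius = min(spec.stem_height // 2, h // 2 - 2, w // 2 - 2)
    for a in range(n_arms):
        angle = 2 * np.pi * a / n_arms + rng.uniform(-0.2, 0.2)
        length = int(rng.integers(max(radius // 2, 2), radius + 1))
        end = (
            int(np.clip(centre[0] + length * np.sin(angle), 0, h - 1)),
            int(np.clip(centre[1] + length * np.cos(angle), 0, w - 1)),
        )
        rr, cc = line(centre[0], centre[1], end[0], end[1])
        mask[rr, cc] = True
    rr, cc = disk(centre, max(spec.stem_thickness, 2), shape=(h, w))
    mask[rr, cc] = True
    return mask


def generate_plant_image(spec: PlantSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one plant image; returns (RGB image, exact ground truth).

    Compositing order: background, pot band, debris, plant — the plant is
    drawn last, so every ground-truth mask pixel is visible in the image.
    Deterministic: the same spec yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = spec.background

    if spec.pot_band_rows > 0 and not spec.top_view:
        image[h - spec.pot_band_rows :, :] = POT_COLOR

    plant = _draw_top_plant(spec, rng) if spec.top_view else _draw_side_plant(spec, rng)

    # debris blobs: disjoint from the plant (2 px clearance) so they stay
    # separate connected components
    debris_color = HARD_DEBRIS_COLOR if spec.hard_noise else SOFT_DEBRIS_COLOR
    forbidden = ndimage.binary_dilation(plant, iterations=3)
    debris_mask = np.zeros((h, w), dtype=bool)
    debris_areas: list[int] = []
    for _ in range(spec.n_debris):
        for _attempt in range(20):
            r = int(rng.integers(spec.debris_radius[0], spec.debris_radius[1] + 1))
            cy = int(rng.integers(r, h - spec.pot_band_rows - r - 1))
            cx = int(rng.integers(r, w - r - 1))
            rr, cc = disk((cy, cx), r, shape=(h, w))
            blob = np.zeros((h, w), dtype=bool)
            blob[rr, cc] = True
            clearance = ndimage.binary_dilation(blob, iterations=2)
            if not (clearance & (forbidden | debris_mask)).any():
                debris_mask |= blob
                debris_areas.append(int(blob.sum()))
                break
    jitter = rng.integers(-10, 11, size=(h, w))
    for c, base in enumerate(debris_color):
        plane = image[:, :, c]
        plane[debris_mask] = np.clip(base + jitter[debris_mask], 0, 255).astype(np.uint8)
    if spec.hard_noise:
        # keep the predicate g > b true after jitter
        gb = image[:, :, 1][debris_mask].astype(int) <= image[:, :, 2][debris_mask].astype(int)
        if gb.any():
            g = image[:, :, 1]
            idx = np.nonzero(debris_mask)
            g[idx[0][gb], idx[1][gb]] = np.minimum(
                image[:, :, 2][idx[0][gb], idx[1][gb]].astype(int) + 20, 255
            ).astype(np.uint8)

    # plant colors: green-dominant, always satisfying g > b
    n_fg = int(plant.sum())
    g_vals = rng.integers(120, 256, size=n_fg)
    b_vals = (g_vals * rng.uniform(0.1, 0.6, size=n_fg)).astype(np.int64)
    r_vals = (g_vals * rng.uniform(0.2, 0.8, size=n_fg)).astype(np.int64)
    fg = np.column_stack([r_vals, g_vals, b_vals]).astype(np.uint8)
    image[plant] = fg

    rows, cols = np.nonzero(plant)
    from .traits import convex_hull, hull_lattice_area  # local import avoids cycle

    hull = convex_hull(np.column_stack([cols, rows]))
    hist = np.zeros((3, 8), dtype=np.int64)
    for c in range(3):
        hist[c] = np.bincount(fg[:, c].astype(int) // 32, minlength=8)
    gt = GroundTruth(
        mask=plant,
        count=n_fg,
        bbox=(int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())),
        moments=_gt_moments(plant),
        hull_area=hull_lattice_area(hull),
        histogram=hist,
        debris_areas=debris_areas,
    )
    return image, gt


DEFAULT_IMTYPES = {"rgbsv": ("0", "90"), "rgbtv": ("0",)}


def generate_tree(
    n_plants: int,
    n_days: int,
    imtypes: Optional[dict] = None,
    seed: int = 0,
    root: str | Path = ".",
    start_date: date = date(2024, 1, 5),
    hard_noise: bool = False,
) -> dict:
    """Write an imaging-platform-style directory tree with known content.

    Layout: ``<id>_<date>/<imtype>/<angle>.png`` under ``root`` (which must
    be empty), plus ``metadata.csv`` (id, genotype, replicate) and
    ``manifest.json`` recording every file with its ground-truth summary.
    Plants grow linearly over days.  Returns the manifest as a dict, whose
    ``template`` entry is a ready-to-use crawler loading template.
    """
    if imtypes is None:
        imtypes = DEFAULT_IMTYPES
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if any(root.iterdir()):
        raise PhenopipeError(f"refusing to write fixtures into nonempty directory {root}")

    from .imgio import write_image

    rng = np.random.default_rng(seed)
    records = []
    meta_rows = []
    for p in range(n_plants):
        plant_id = f"p{p + 1:03d}"
        meta_rows.append(
            {
                "id": plant_id,
                "genotype": f"G{p % max(n_plants // 2, 1) + 1}",
                "replicate": p % 3 + 1,
            }
        )
        base_height = int(rng.integers(50, 80))
        for d in range(n_days):
            day = start_date + timedelta(days=d)
            for imtype, angles in imtypes.items():
                for angle in angles:
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    spec = PlantSpec(
                        seed=sub_seed,
                        stem_height=base_height + 8 * d,
                        n_leaves=3 + d,
                        top_view=imtype.endswith("tv"),
                        hard_noise=hard_noise,
                    )
                    image, gt = generate_plant_image(spec)
                    rel = Path(f"{plant_id}_{day.isoformat()}") / imtype / f"{angle}.png"
                    (root / rel).parent.mkdir(parents=True, exist_ok=True)
                    write_image(root / rel, image)
                    records.append(
                        {
                            "id": plant_id,
                            "date": day.isoformat(),
                            "imtype": imtype,
                            "angle": str(angle),
                            "path": str(rel),
                            "count": gt.count,
                            "bbox": list(gt.bbox),
                            "moments": gt.moments,
                            "hull_area": gt.hull_area,
                            "debris_areas": gt.debris_areas,
                        }
                    )
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(root / "metadata.csv", index=False)
    manifest = {
        "seed": seed,
        "n_plants": n_plants,
        "n_days": n_days,
        "records": records,
        "template": {
            "base_path": str(root),
            "pattern": TREE_PATTERN,
            "metadata": "metadata.csv",
            "key_column": "id",
        },
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_trait_table(
    k_groups: int,
    n_per_group: int,
    effect_size: float,
    seed: int = 0,
    n_traits: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-partition trait table for clustering and ANOVA tests.

    Observations are multivariate normal with unit within-group standard
    deviation; consecutive group means are ``effect_size`` apart along the
    first trait axis, so the planted separation is ``effect_size`` · σ.
    Returns (table, true group labels); deterministic per seed.
    """
    if k_groups < 2:
        raise ArgumentError(f"need k_groups >= 2, got {k_groups}")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for g in range(k_groups):
        centre = np.zeros(n_traits)
        centre[0] = g * effect_size
        rows.append(rng.normal(loc=centre, scale=1.0, size=(n_per_group, n_traits)))
        labels.extend([g] * n_per_group)
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=[f"t{i}" for i in range(n_traits)])
    return table, np.asarray(labels)
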