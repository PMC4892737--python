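"""Digital trait extraction: moments, dimensions, hull, histograms, catalog."""

import numpy as np
import pytest

from phenopipe.errors import ArgumentError, EmptyMaskError, MissingViewError
from phenopipe.traits import (
    TRAIT_FORMULAS,
    center_of_mass,
    color_histogram,
    composite_traits,
    convex_hull,
    convex_hull_metrics,
    dimensions,
    hull_lattice_area,
    pixel_area,
    projected_shoot_area,
    raw_moments,
)

from conftest import random_mask


def brute_force_moments(mask, max_order=3):
    """Double-loop oracle: M_ij = sum over foreground of x^i y^j."""
    m = {}
    h, w = mask.shape
    for i in range(max_order + 1):
        for j in range(max_order + 1):
            total = 0
            for y in range(h):
                for x in range(w):
                    if mask[y, x]:
                        total += x**i * y**j
            m[f"M{i}{j}"] = total
    return m


class TestRawMoments:
    def test_single_pixel(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 3] = True
        m = raw_moments(mask)
        assert (m[0, 0], m[1, 0], m[0, 1], m[1, 1]) == (1, 3, 4, 12)

    def test_two_by_two_block(self):
        mask = np.zeros((4, 4), bool)
        mask[0:2, 0:2] = True
        m = raw_moments(mask)
        assert (m[0, 0], m[1, 0], m[0, 1], m[1, 1]) == (4, 2, 2, 1)

    def test_empty_mask_all_zero(self):
        m = raw_moments(np.zeros((5, 5), bool))
        assert all(v == 0 for v in m.as_dict().values())

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            mask = random_mask(rng, (50, 50), 0.2)
            assert raw_moments(mask).as_dict() == brute_force_moments(mask)

    def test_translation_rule_exact(self, rng):
        """M10' = M10 + dx*M00 and M01' = M01 + dy*M00 for integer shifts."""
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = random_mask(rng, (10, 10), 0.5)
        dx, dy = 7, 11
        shifted = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        m0, m1 = raw_moments(mask), raw_moments(shifted)
        assert m1[1, 0] == m0[1, 0] + dx * m0[0, 0]
        assert m1[0, 1] == m0[0, 1] + dy * m0[0, 0]

    def test_large_coordinates_stay_exact(self):
        """Order-3 products near the int64 edge fall back to exact bigints."""
        mask = np.zeros((1, 200000), bool)
        mask[0, -2000:] = True
        m = raw_moments(mask)
        expected = sum(x**3 for x in range(198000, 200000))
        assert m[3, 0] == expected  # > 2**63, wrong under modular arithmetic


class TestCentroidAndDimensions:
    def test_single_pixel_centroid(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 3] = True
        assert center_of_mass(raw_moments(mask)) == (3.0, 4.0)

    def test_symmetric_square_centroid(self):
        mask = np.zeros((21, 21), bool)
        mask[8:13, 8:13] = True
        assert center_of_mass(raw_moments(mask)) == (10.0, 10.0)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            center_of_mass(raw_moments(np.zeros((3, 3), bool)))

    def test_translation_shifts_centroid_exactly(self, rng):
        mask = np.zeros((30, 30), bool)
        mask[3:10, 3:10] = random_mask(rng, (7, 7), 0.6)
        x0, y0 = center_of_mass(raw_moments(mask))
        shifted = np.roll(np.roll(mask, 5, axis=0), 9, axis=1)
        x1, y1 = center_of_mass(raw_moments(shifted))
        assert (x1 - x0, y1 - y0) == (9.0, 5.0)

    def test_dimensions(self):
        mask = np.zeros((10, 12), bool)
        mask[2:6, 3:9] = True
        assert dimensions(mask) == (4, 6)
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert dimensions(single) == (1, 1)

    def test_dimensions_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            dimensions(np.zeros((3, 3), bool))


class TestAreas:
    def test_pixel_area_basics(self):
        assert pixel_area(np.zeros((4, 4), bool)) == 0
        assert pixel_area(np.ones((10, 10), bool)) == 100

    def test_pixel_area_equals_m00(self, rng):
        for _ in range(10):
            mask = random_mask(rng, (30, 30), rng.uniform(0.1, 0.9))
            assert pixel_area(mask) == raw_moments(mask).area

    def test_projected_shoot_area_is_the_sum(self):
        assert projected_shoot_area(0, 0) == 0
        assert projected_shoot_area(1200, 1350) == 2550

    def test_projected_shoot_area_symmetric(self, rng):
        a, b = int(rng.integers(0, 5000)), int(rng.integers(0, 5000))
        assert projected_shoot_area(a, b) == projected_shoot_area(b, a)

    def test_negative_area_rejected(self):
        with pytest.raises(ArgumentError):
            projected_shoot_area(-1, 5)


def brute_force_hull_count(mask):
    """Oracle: exact point-in-hull test for every pixel center via cross
    products against every hull edge of the foreground point set."""
    rows, cols = np.nonzero(mask)
    pts = list(zip(cols.tolist(), rows.tolist()))
    hull = convex_hull(np.array(pts))
    count = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if len(hull) == 1:
                inside = (x, y) == tuple(hull[0])
            elif len(hull) == 2:
                (ax, ay), (bx, by) = hull
                on_line = (bx - ax) * (y - ay) - (by - ay) * (x - ax) == 0
                inside = (
                    on_line
                    and min(ax, bx) <= x <= max(ax, bx)
                    and min(ay, by) <= y <= max(ay, by)
                )
            else:
                inside = True
                for k in range(len(hull)):
                    a, b = hull[k], hull[(k + 1) % len(hull)]
                    if (b[0] - a[0]) * (y - a[1]) - (b[1] - a[1]) * (x - a[0]) < 0:
                        inside = False
                        break
            count += inside
    return count


class TestConvexHull:
    def test_filled_rectangle_density_one(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 2:10] = True
        hull_area, density = convex_hull_metrics(mask)
        assert hull_area == 48 and density == 1.0

    def test_two_corner_pixels_sparse(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = mask[9, 9] = True
        hull_area, density = convex_hull_metrics(mask)
        assert hull_area == 10  # the diagonal lattice points
        assert density == pytest.approx(0.2)

    def test_matches_point_in_hull_oracle(self, rng):
        for _ in range(15):
            mask = random_mask(rng, (15, 15), rng.uniform(0.05, 0.5))
            if not mask.any():
                continue
            hull_area, _ = convex_hull_metrics(mask)
            assert hull_area == brute_force_hull_count(mask)

    def test_hull_area_bounds_pixel_area(self, rng):
        for _ in range(10):
            mask = random_mask(rng, (20, 20), 0.3)
            if not mask.any():
                continue
            hull_area, density = convex_hull_metrics(mask)
            assert hull_area >= pixel_area(mask)
            assert 0 < density <= 1

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            convex_hull_metrics(np.zeros((4, 4), bool))

    def test_degenerate_hulls(self):
        point = convex_hull(np.array([[3, 3]]))
        assert hull_lattice_area(point) == 1
        segment = convex_hull(np.array([[0, 0], [4, 0], [2, 0]]))
        assert hull_lattice_area(segment) == 5


class TestColorHistogram:
    def test_uniform_green_single_bin(self):
        img = np.zeros((6, 6, 3), np.uint8)
        img[..., 1] = 200
        hist = color_histogram(img, np.ones((6, 6), bool), bins=8)
        assert hist.counts[1, 200 // 32] == 36
        assert hist.counts[1].sum() == 36
        assert hist.proportions[1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_mask_flagged(self):
        img = np.zeros((4, 4, 3), np.uint8)
        hist = color_histogram(img, np.zeros((4, 4), bool))
        assert hist.empty and (hist.counts == 0).all()

    def test_counts_sum_to_area_random(self, rng):
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        mask = random_mask(rng, (20, 20), 0.4)
        hist = color_histogram(img, mask, bins=16)
        assert (hist.counts.sum(axis=1) == pixel_area(mask)).all()
        # brute-force recount of one channel/bin
        fg = img[mask]
        assert hist.counts[2, 3] == int(((fg[:, 2] // 16) == 3).sum())

    @pytest.mark.parametrize("bins", [0, 3, 7, 257])
    def test_bins_must_divide_256(self, bins):
        with pytest.raises(ArgumentError):
            color_histogram(np.zeros((2, 2, 3), np.uint8), np.ones((2, 2), bool), bins)


class TestCompositeTraits:
    def _square_views(self):
        sv = np.zeros((20, 20), bool)
        sv[5:15, 5:15] = True
        return {"sv0": sv, "sv90": sv.copy(), "tv": sv.copy()}

    def test_square_plant_ratios(self):
        out = composite_traits(self._square_views())
        assert out["GH1"] == 1.0
        assert out["Den1_SV"] == 1.0
        assert out["Den2_SV"] == 1.0

    def test_psa_is_sum_of_side_view_areas(self):
        views = self._square_views()
        out = composite_traits(views)
        assert out["PSA"] == pixel_area(views["sv0"]) + pixel_area(views["sv90"])

    def test_missing_view_listed(self):
        views = self._square_views()
        del views["tv"]
        with pytest.raises(MissingViewError, match="tv"):
            composite_traits(views)

    def test_catalog_complete_and_ratios_in_range(self, rng):
        from phenopipe.synth import PlantSpec, generate_plant_image

        for seed in range(20):
            _, sv0 = generate_plant_image(PlantSpec(seed=seed))
            _, sv90 = generate_plant_image(PlantSpec(seed=seed + 1000))
            _, tv = generate_plant_image(PlantSpec(seed=seed + 2000, top_view=True))
            out = composite_traits({"sv0": sv0.mask, "sv90": sv90.mask, "tv": tv.mask})
            for name in TRAIT_FORMULAS:
                assert name in out
            for name in ("Den1_SV", "Den1_TV", "Den2_SV", "Den2_TV", "GH2", "GH3"):
                assert 0 < out[name] <= 1, (name, out[name])
            assert 0 <= out["GH4"] < 1
            assert out["GH1"] > 0

    def test_border_padding_invariance(self, rng):
        """Padding with background shifts centroid moments only; the named
        shape traits are unchanged."""
        views = {
            k: np.pad(v, 4) for k, v in self._square_views().items()
        }
        base = composite_traits(self._square_views())
        padded = composite_traits(views)
        for name in TRAIT_FORMULAS:
            assert padded[name] == pytest.approx(base[name])
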