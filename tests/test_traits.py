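"""The measurement pipeline: segmentation, contour geometry, aggregation."""

import math

import numpy as np
import pytest

from grainscan import synth, traits
from grainscan.traits import (
    Contour,
    GrainTraits,
    aggregate_panicle,
    binarize,
    derived_traits,
    extract_grain_traits,
    grain_area,
    grain_length,
    grain_perimeter,
    grain_width,
    largest_outer_contour,
    otsu_threshold,
    red_channel,
    thousand_grain_stats,
)
from tests.conftest import MM150, MM600


def brute_force_otsu(gray: np.ndarray) -> int:
    """Independent oracle: exhaustively split the raw pixel array."""
    flat = gray.ravel().astype(np.float64)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(flat), len(hi) / len(flat)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestRedChannel:
    def test_returns_r_unchanged(self):
        px = np.zeros((2, 2, 3), np.uint8)
        px[0, 0] = (200, 10, 10)
        assert red_channel(px)[0, 0] == 200

    def test_pure_blue_is_black(self):
        px = np.zeros((4, 4, 3), np.uint8)
        px[..., 2] = 255
        assert red_channel(px).max() == 0

    def test_grain_contrast_strongest_in_red(self, grain_600dpi):
        _, crop, mask = grain_600dpi
        contrast = [
            float(crop[..., c][mask].mean()) - float(crop[..., c][~mask].mean())
            for c in range(3)
        ]
        assert contrast[0] >= contrast[2]

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            red_channel(np.zeros((4, 4), np.uint8))


class TestOtsu:
    def test_two_level_image(self):
        gray = np.full((10, 10), 40, np.uint8)
        gray[:5] = 200
        t = otsu_threshold(gray)
        assert 40 <= t <= 199
        assert np.array_equal(binarize(gray, t), gray == 200)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gray = rng.integers(0, 256, (24, 24)).astype(np.uint8)
            assert otsu_threshold(gray) == brute_force_otsu(gray)

    def test_grain_crop_segmentation_quality(self, grain_600dpi):
        _, crop, mask = grain_600dpi
        gray = red_channel(crop)
        fg = binarize(gray, otsu_threshold(gray))
        jacc = (fg & mask).sum() / (fg | mask).sum()
        assert jacc >= 0.98

    def test_constant_image_degenerate(self):
        with pytest.raises(traits.TraitExtractionError):
            otsu_threshold(np.full((8, 8), 100, np.uint8))


class TestContour:
    def test_filled_square(self):
        sq = np.zeros((14, 14), bool)
        sq[2:12, 2:12] = True
        c = largest_outer_contour(sq)
        x, y = c.points[:, 0], c.points[:, 1]
        signed = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed == pytest.approx(100.0, abs=1.0)  # corner-cut polygon

    def test_largest_of_two_blobs(self):
        img = np.zeros((30, 30), bool)
        img[2:12, 2:12] = True  # area 100
        img[20:25, 20:26] = True  # area 30
        c = largest_outer_contour(img)
        assert c.points[:, 0].max() < 15  # comes from the large blob

    def test_holes_ignored(self):
        img = np.zeros((20, 20), bool)
        img[2:18, 2:18] = True
        img[8:12, 8:12] = False  # interior hole
        c = largest_outer_contour(img)
        # outer boundary only: all points near the outer rim
        r = np.hypot(c.points[:, 0] - 9.5, c.points[:, 1] - 9.5)
        assert r.min() > 5.0

    def test_empty_foreground(self):
        with pytest.raises(traits.TraitExtractionError):
            largest_outer_contour(np.zeros((5, 5), bool))


class TestLengthWidth:
    def test_rectangle_diagonal(self):
        r = np.zeros((14, 34), bool)
        r[2:12, 2:32] = True
        c = largest_outer_contour(r)
        L, _ = grain_length(c, 1.0)
        assert L == pytest.approx(math.hypot(30, 10), abs=1.0)

    def test_digital_circle_diameter(self):
        yy, xx = np.mgrid[0:109, 0:109]
        disk = ((xx - 54) ** 2 + (yy - 54) ** 2) <= 50**2
        c = largest_outer_contour(disk)
        L, axis = grain_length(c, 1.0)
        W = grain_width(c, axis, 1.0)
        assert abs(L - 100) <= 1.0 + 1e-9
        assert abs(W - 100) <= 1.5

    def test_rendered_ellipse_axes(self, rng):
        # 2a = 200 px, 2b = 70 px at this scale
        model = synth.GrainModel(200 * MM600, 70 * MM600, shape_n=2.0,
                                 orientation=0.3, noise_sd=0.0)
        crop, mask = synth.render_grain(model, MM600, rng=rng)
        c = largest_outer_contour(mask)
        L, axis = grain_length(c, 1.0)
        W = grain_width(c, axis, 1.0)
        assert L == pytest.approx(200, rel=0.02)
        assert W == pytest.approx(70, rel=0.02)

    def test_thin_line_width(self):
        line = np.zeros((6, 24), bool)
        line[3, 2:22] = True
        c = largest_outer_contour(line)
        L, axis = grain_length(c, 1.0)
        W = grain_width(c, axis, 1.0)
        assert W <= 2.0

    def test_calipers_equals_bruteforce(self, rng):
        for _ in range(5):
            model = synth.sample_grain(synth.GrainDistribution(), rng)
            _, mask = synth.render_grain(model, MM150, rng=rng)
            c = largest_outer_contour(mask)
            L, _ = grain_length(c, 1.0)
            pts = c.points
            brute = 0.0
            for i in range(len(pts)):
                d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
                if len(d):
                    brute = max(brute, float(d.max()))
            assert L == pytest.approx(brute, abs=1e-9)


class TestAreaPerimeter:
    def test_square_golden_values(self):
        sq = np.zeros((14, 14), bool)
        sq[2:12, 2:12] = True
        assert grain_area(sq, 1.0) == 100.0
        P = grain_perimeter(largest_outer_contour(sq), 1.0)
        assert 36.0 <= P <= 40.0
        assert P == pytest.approx(36.17, abs=0.01)  # frozen for this tracer

    def test_circle_analytics(self):
        yy, xx = np.mgrid[0:109, 0:109]
        disk = ((xx - 54) ** 2 + (yy - 54) ** 2) <= 50**2
        assert grain_area(disk, 1.0) == pytest.approx(math.pi * 2500, rel=0.02)
        P = grain_perimeter(largest_outer_contour(disk), 1.0)
        assert P == pytest.approx(2 * math.pi * 50, rel=0.02)

    def test_single_pixel(self):
        px = np.zeros((5, 5), bool)
        px[2, 2] = True
        assert grain_area(px, 1.0) == 1.0

    def test_empty(self):
        with pytest.raises(traits.TraitExtractionError):
            grain_area(np.zeros((4, 4), bool), 1.0)


class TestDerivedTraits:
    def test_table_mean_consistency(self):
        d = derived_traits(8.607, 2.770, 18.140, 21.313)
        assert d.ap_ratio == pytest.approx(0.851, abs=5e-4)

    def test_ideal_circle_circularity(self):
        r = 3.0
        d = derived_traits(2 * r, 2 * r, math.pi * r**2, 2 * math.pi * r)
        assert d.circularity == pytest.approx(1.0, abs=1e-12)

    def test_equivalent_ellipse_minor(self):
        d = derived_traits(8.0, 3.0, 6 * math.pi, 20.0)
        assert d.eq_minor == pytest.approx(3.0, abs=1e-12)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            derived_traits(8.0, 0.0, 18.0, 21.0)


class TestExtract:
    def test_recovery_within_2pct(self, rng):
        model = synth.GrainModel(8.6, 2.8, orientation=1.1, noise_sd=5.0)
        crop, _ = synth.render_grain(model, MM600, rng=rng)
        t = extract_grain_traits(crop, MM600)
        assert t.length == pytest.approx(8.6, rel=0.02)
        assert t.width == pytest.approx(2.8, rel=0.02)

    def test_blank_crop_explicit_error(self):
        blank = np.full((64, 64, 3), 30, np.uint8)
        with pytest.raises(traits.TraitExtractionError):
            extract_grain_traits(blank, MM600)

    def test_deterministic(self, grain_600dpi):
        _, crop, _ = grain_600dpi
        a = extract_grain_traits(crop, MM600)
        b = extract_grain_traits(crop, MM600)
        assert a == b

    def test_rotation_robustness(self, rng):
        vals = []
        for k in range(8):
            model = synth.GrainModel(8.6, 2.8, orientation=k * math.pi / 8,
                                     noise_sd=0.0)
            crop, _ = synth.render_grain(model, MM600, rng=rng)
            t = extract_grain_traits(crop, MM600)
            vals.append((t.length, t.width))
        L = np.array([v[0] for v in vals])
        W = np.array([v[1] for v in vals])
        assert (L.max() - L.min()) / L.mean() < 0.03
        assert (W.max() - W.min()) / W.mean() < 0.03

    def test_scale_equivariance(self, rng):
        model = synth.GrainModel(8.6, 2.8, orientation=0.4, noise_sd=0.0)
        t600 = extract_grain_traits(synth.render_grain(model, MM600, rng=rng)[0], MM600)
        mm300 = 25.4 / 300
        t300 = extract_grain_traits(synth.render_grain(model, mm300, rng=rng)[0], mm300)
        for attr in ("length", "width", "area", "perimeter"):
            a, b = getattr(t600, attr), getattr(t300, attr)
            assert abs(a - b) / a < 0.03

    def test_length_geq_width_many_grains(self):
        rng = np.random.default_rng(8)
        dist = synth.GrainDistribution()
        for _ in range(1000):
            model = synth.sample_grain(dist, rng)
            crop, _ = synth.render_grain(model, MM150, rng=rng)
            t = extract_grain_traits(crop, MM150)
            assert t.length >= t.width
            assert t.circularity <= 1.05

    def test_circularity_approaches_one_for_disks(self):
        circs = []
        for r in (25, 100):
            d_mm = 2 * r * MM150
            model = synth.GrainModel(d_mm, d_mm, shape_n=2.0, noise_sd=0.0)
            crop, _ = synth.render_grain(model, MM150, rng=np.random.default_rng(0))
            circs.append(extract_grain_traits(crop, MM150).circularity)
        assert circs[1] > 0.97
        assert abs(circs[1] - 1.0) < abs(circs[0] - 1.0) + 0.02


class TestAggregate:
    def _grain(self, length, width):
        area, perim = 18.0, 21.0
        d = derived_traits(length, width, area, perim)
        return GrainTraits(length, width, area, perim, d.lw_ratio, d.ap_ratio,
                           d.circularity, d.eq_major, d.eq_minor)

    def test_single_grain_zero_sd(self):
        p = aggregate_panicle([self._grain(8.0, 3.0)])
        assert p.GN == 1
        assert p.SGL == p.SGW == p.SGPA == 0.0

    def test_two_grains_hand_values(self):
        p = aggregate_panicle([self._grain(8.0, 3.0), self._grain(10.0, 3.0)])
        assert p.MGL == pytest.approx(9.0)
        assert p.SGL == pytest.approx(math.sqrt(2.0))

    def test_permutation_invariant(self, rng):
        grains = [self._grain(5 + 6 * rng.random(), 2 + rng.random())
                  for _ in range(20)]
        a = aggregate_panicle(grains)
        b = aggregate_panicle(list(reversed(grains)))
        for name in traits.PANICLE_TRAIT_ORDER:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_population_sd_convention(self):
        grains = [self._grain(8.0, 3.0), self._grain(10.0, 3.0)]
        p = aggregate_panicle(grains, sd="population")
        assert p.SGL == pytest.approx(1.0)

    def test_sample_mean_tracks_generator(self):
        rng = np.random.default_rng(21)
        dist = synth.GrainDistribution()
        measured = []
        for _ in range(200):
            model = synth.sample_grain(dist, rng)
            crop, _ = synth.render_grain(model, MM150, rng=rng)
            measured.append(extract_grain_traits(crop, MM150))
        p = aggregate_panicle(measured)
        se = 0.589 / math.sqrt(200)
        # 3 se of sampling noise plus the ~1% measurement scale slack
        assert abs(p.MGL - 8.607) < 3 * se + 0.01 * 8.607

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_panicle([])

    def test_fifteen_trait_row_order(self):
        p = aggregate_panicle([self._grain(8.0, 3.0)])
        assert list(p.as_row().keys()) == list(traits.PANICLE_TRAIT_ORDER)
        assert len(p.as_row()) == 15


class TestThousandGrain:
    def _pool(self, n, rng=None, identical=False):
        if identical:
            return [TestAggregate()._grain(8.0, 3.0)] * n
        rng = rng or np.random.default_rng(0)
        return [
            TestAggregate()._grain(5.0 + 6.0 * rng.random(), 2.0 + 2.0 * rng.random())
            for _ in range(n)
        ]

    def test_identical_pool_single_bin(self):
        out = thousand_grain_stats(self._pool(1000, identical=True), seed=0)
        counts, _ = out["histograms"]["length_mm"]
        assert (counts > 0).sum() == 1

    def test_counts_sum_to_sample_size(self):
        out = thousand_grain_stats(self._pool(1500), seed=1)
        for trait in ("length_mm", "width_mm", "lw_ratio"):
            assert out["histograms"][trait][0].sum() == 1000

    def test_uniform_pool_flat_histogram(self):
        rng = np.random.default_rng(3)
        pool = self._pool(6000, rng)
        edges = np.linspace(5.0, 11.0, 7)
        out = thousand_grain_stats(
            pool, bins={"length_mm": edges,
                        "width_mm": np.linspace(2, 4, 5),
                        "lw_ratio": np.linspace(1, 6, 6)},
            seed=2,
        )
        counts, _ = out["histograms"]["length_mm"]
        n, k = 1000, 6
        p = 1 / k
        sigma = math.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3 * sigma)

    def test_small_pool_warns(self):
        with pytest.warns(UserWarning):
            thousand_grain_stats(self._pool(50), n=1000, seed=0)

    def test_deterministic_per_seed(self):
        pool = self._pool(1200)
        a = thousand_grain_stats(pool, seed=9)
        b = thousand_grain_stats(pool, seed=9)
        assert np.array_equal(a["histograms"]["length_mm"][0],
                              b["histograms"]["length_mm"][0])
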