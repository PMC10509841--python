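"""Properties of the per-pixel redness index, distributions and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cptquant import redness as rd
from cptquant.segmentation import EyeSegmentation


def make_seg(mask, shape=None):
    shape = shape or mask.shape
    return EyeSegmentation(
        sclera_mask=mask,
        iris_mask=np.zeros(shape, bool),
        eye_open=True,
        quality_flags=frozenset(),
    )


class TestPixelRedness:
    @given(st.integers(0, 255))
    @settings(deadline=None)
    def test_achromatic_pixels_score_zero(self, level):
        # the attainable pixel domain: 8-bit channel values normalized to [0, 1]
        v = level / 255.0
        assert rd.pixel_redness(v, v, v) == pytest.approx(0.0, abs=1e-12)

    def test_achromatic_grid_is_zero(self):
        v = np.linspace(0.0, 1.0, 256)
        assert np.allclose(rd.pixel_redness(v, v, v), 0.0)

    def test_black_pixel_limit_convention(self):
        assert rd.pixel_redness(0.0, 0.0, 0.0) == 0.0

    def test_unit_magnitude_pixels_score_zero(self):
        # s = 1 annihilates the (1-s)^2 weight, e.g. saturated pure red
        assert rd.pixel_redness(1.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)
        r = 0.6
        g = b = np.sqrt((1.0 - r * r) / 2.0)
        assert rd.pixel_redness(r, g, b) == pytest.approx(0.0, abs=1e-12)

    def test_sign_follows_red_excess_over_quadratic_mean(self):
        rng = np.random.default_rng(0)
        r, g, b = rng.uniform(0.01, 0.99, (3, 500))
        s = np.sqrt(r * r + g * g + b * b)
        keep = (s > 1e-6) & (np.abs(s - 1.0) > 1e-6)
        vals = rd.pixel_redness(r, g, b)[keep]
        excess = (r - np.sqrt((g * g + b * b) / 2.0))[keep]
        assert np.all(np.sign(vals) == np.sign(excess))

    def test_overexposure_suppression_along_chromaticity_ray(self):
        # scale a fixed reddish chromaticity toward unit magnitude: R -> 0
        base = np.array([0.8, 0.4, 0.3])
        base = base / np.linalg.norm(base)
        scales = np.array([0.5, 0.9, 0.99, 0.999])
        vals = [abs(rd.pixel_redness(*(s * base))) for s in scales]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] < 1e-4

    def test_pure_red_maximum_matches_frozen_constant(self):
        grid = np.linspace(0.0, 1.0, 10_002)[1:-1]  # 1e4 points in (0, 1)
        vals = rd.pixel_redness(grid, np.zeros_like(grid), np.zeros_like(grid))
        assert vals.max() == pytest.approx(rd.PURE_RED_GRID_MAX, rel=1e-12)

    def test_out_of_range_channel_rejected(self):
        with pytest.raises(ValueError):
            rd.pixel_redness(1.2, 0.0, 0.0)


class TestRednessMap:
    def test_uniform_gray_sclera_gives_zero_map(self):
        img = np.full((20, 30, 3), 128, np.uint8)
        mask = np.zeros((20, 30), bool)
        mask[5:15, 5:25] = True
        m = rd.redness_map(img, make_seg(mask))
        assert np.allclose(m.mask_values, 0.0)

    def test_mask_pixel_count_contract(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        mask = rng.random((16, 16)) < 0.4
        mask[0, 0] = True
        m = rd.redness_map(img, make_seg(mask))
        assert m.mask_values.size == mask.sum()

    def test_flagged_segmentation_refused(self):
        img = np.zeros((8, 8, 3), np.uint8)
        seg = EyeSegmentation(
            sclera_mask=np.ones((8, 8), bool),
            iris_mask=np.zeros((8, 8), bool),
            eye_open=False,
            quality_flags=frozenset({"eye_missing"}),
        )
        with pytest.raises(ValueError, match="segmentation failed"):
            rd.redness_map(img, seg)


class TestRednessDistribution:
    def test_all_zero_map_occupies_single_bin_at_zero(self):
        d = rd.distribution_from_values(np.zeros(100))
        assert d.n_occupied_bins == 1
        assert d.mean_redness == 0.0
        occupied = np.flatnonzero(d.counts)[0]
        assert d.bin_edges[occupied] <= 0.0 < d.bin_edges[occupied + 1]

    def test_pooling_two_identical_maps_doubles_counts(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (12, 12, 3), dtype=np.uint8)
        mask = np.ones((12, 12), bool)
        m = rd.redness_map(img, make_seg(mask))
        one = rd.redness_distribution([m])
        two = rd.redness_distribution([m, m])
        assert np.array_equal(two.counts, 2 * one.counts)
        assert two.mean_redness == pytest.approx(one.mean_redness)

    def test_pooled_mean_is_count_weighted_mean(self):
        rng = np.random.default_rng(3)
        maps = []
        for i in range(3):
            img = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
            mask = rng.random((10, 10)) < 0.5
            mask[0, 0] = True
            maps.append(rd.redness_map(img, make_seg(mask)))
        pooled = rd.redness_distribution(maps)
        weights = np.array([m.mask_values.size for m in maps], float)
        means = np.array([m.mean for m in maps])
        assert pooled.mean_redness == pytest.approx((weights * means).sum() / weights.sum())

    def test_counts_sum_to_pixels_and_shift_moves_mean(self):
        rng = np.random.default_rng(4)
        d = rd.distribution_from_values(rng.normal(0.1, 0.05, 1000))
        assert d.counts.sum() == d.n_pixels == 1000
        shifted = d.shifted(5 * d.bin_width)
        assert shifted.mean_redness == pytest.approx(d.mean_redness + 5 * d.bin_width)
        assert shifted.counts.sum() == d.n_pixels

    def test_empty_pooled_mask_refused(self):
        with pytest.raises(ValueError):
            rd.distribution_from_values(np.empty(0))
        with pytest.raises(ValueError):
            rd.redness_distribution([])


def brute_force_gradient(values, mask, k):
    """Independent enumeration of squared differences at lag k."""
    h, w = values.shape
    out = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            if x + k < w and mask[y, x + k]:
                out.append((values[y, x + k] - values[y, x]) ** 2)
            if y + k < h and mask[y + k, x]:
                out.append((values[y + k, x] - values[y, x]) ** 2)
    return np.array(out)


class TestGradientDistribution:
    def test_constant_map_concentrates_at_zero(self):
        m = rd.RednessMap(values=np.full((12, 12), 0.2), mask=np.ones((12, 12), bool))
        g = rd.gradient_distribution(m)
        for k in rd.GRADIENT_STEPS:
            assert g.total(k) == g.n_pairs[k] > 0
            assert g.counts[k][0] == g.n_pairs[k]  # all mass in the 0 bin

    def test_step_edge_oracle_on_toy_map(self):
        # vertical step edge of height h: horizontal squared diffs are {0, h^2},
        # with rows x k pairs straddling the edge at lag k
        h_edge = 0.3
        values = np.zeros((10, 10))
        values[:, 5:] = h_edge
        mask = np.ones((10, 10), bool)
        m = rd.RednessMap(values=values, mask=mask)
        g = rd.gradient_distribution(m)
        for k in rd.GRADIENT_STEPS:
            sq = brute_force_gradient(values, mask, k)
            assert g.total(k) == sq.size
            n_hits = int((sq > 1e-12).sum())
            assert n_hits == 10 * k
            assert np.allclose(sq[sq > 1e-12], h_edge**2)
            # histogram mass above zero matches the enumeration
            assert g.counts[k][1:].sum() == n_hits

    def test_pair_count_conservation_random_masks(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.2, (15, 13))
        mask = rng.random((15, 13)) < 0.6
        mask[0, 0] = True
        g = rd.gradient_distribution(rd.RednessMap(values=values, mask=mask))
        for k in rd.GRADIENT_STEPS:
            assert g.total(k) == brute_force_gradient(values, mask, k).size

    def test_thin_mask_yields_empty_flagged_step(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        g = rd.gradient_distribution(rd.RednessMap(values=np.zeros((8, 8)), mask=mask))
        assert set(g.empty_steps) == set(rd.GRADIENT_STEPS)

    def test_vessel_stroke_adds_mass_above_zero(self):
        from cptquant.synthetic import EyePhantomSpec, render_eye_image

        base = dict(diffuse_redness=0.05, noise_sd=0.0, seed=42)
        plain = EyePhantomSpec(vessel_count=0, **base)
        veined = EyePhantomSpec(vessel_count=8, **base)
        masses = []
        for spec in (plain, veined):
            img, gt = render_eye_image(spec)
            m = rd.redness_map(img, make_seg(gt.sclera_mask))
            g = rd.gradient_distribution(m)
            masses.append(g.counts[1][1:].sum() / g.n_pairs[1])
        assert masses[1] > masses[0]
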