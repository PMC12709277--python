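import numpy as np
import pytest

from haloseg import (
    HaloCorrectionConfig,
    directional_gradients,
    extract_contours,
    halo_correct,
    halo_correct_result,
)
from haloseg.halo import DIRECTIONS


def radial_field(size, center, profile):
    """Rotationally symmetric image v(r) from a 1-D profile function."""
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - center, xx - center)
    return profile(r)


def disk_mask(size, center, radius):
    yy, xx = np.mgrid[0:size, 0:size]
    return (np.hypot(yy - center, xx - center) <= radius).astype(np.uint8)


def ridge_profile(r):
    """Plateau 100 to r=10, linear rise to 140 at r=14, linear fall to 80."""
    return np.where(
        r <= 10, 100.0, np.where(r <= 14, 100.0 + 10.0 * (r - 10.0), np.maximum(80.0, 140.0 - 15.0 * (r - 14.0)))
    )


class TestExtractContours:
    def test_empty_mask(self):
        assert extract_contours(np.zeros((6, 6), dtype=np.uint8)) == []

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = 1
        assert extract_contours(mask) == [(2, 3)]

    def test_solid_square_perimeter(self):
        mask = np.zeros((11, 11), dtype=np.uint8)
        mask[3:8, 3:8] = 1
        points = set(extract_contours(mask))
        # brute-force: foreground pixels with a 4-neighbor outside the mask
        expected = set()
        for r in range(11):
            for c in range(11):
                if not mask[r, c]:
                    continue
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < 11 and 0 <= cc < 11) or not mask[rr, cc]:
                        expected.add((r, c))
        assert points == expected
        assert len(points) == 16

    def test_border_foreground_is_contour(self):
        mask = np.ones((4, 4), dtype=np.uint8)
        assert len(extract_contours(mask)) == 12  # all but the 2x2 interior


class TestDirectionalGradients:
    def test_flat_field(self):
        g = directional_gradients(np.full((7, 7), 9.0), (3, 3))
        np.testing.assert_array_equal(g, 0.0)

    def test_horizontal_ramp(self):
        img = np.tile(np.arange(9, dtype=float), (9, 1))
        g = dict(zip(DIRECTIONS, directional_gradients(img, (4, 4))))
        assert g[(0, 1)] == 1 and g[(0, -1)] == -1
        assert g[(-1, 0)] == 0 and g[(1, 0)] == 0
        assert g[(-1, 1)] == 1 and g[(1, -1)] == -1

    def test_matches_direct_subtraction(self, rng):
        img = rng.uniform(0, 100, size=(9, 9))
        g = directional_gradients(img, (4, 4))
        for i, (dr, dc) in enumerate(DIRECTIONS):
            assert g[i] == pytest.approx(img[4 + dr, 4 + dc] - img[4, 4])

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(ValueError):
            directional_gradients(np.zeros((5, 5)), (5, 0))

    def test_border_point_yields_neg_inf(self):
        g = dict(zip(DIRECTIONS, directional_gradients(np.zeros((5, 5)), (0, 0))))
        assert g[(-1, 0)] == -np.inf and g[(0, -1)] == -np.inf


class TestHaloCorrectGrow:
    def test_immediate_termination_on_plateau_edge(self):
        # foreground plateau is brighter than everything outside: all
        # outward gradients negative, nothing grows
        img = np.full((20, 20), 50.0)
        img[5:15, 5:15] = 120.0
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        res = halo_correct_result(img, mask, HaloCorrectionConfig(direction="grow"))
        np.testing.assert_array_equal(res.mask, mask)
        assert res.converged and res.iterations == 0

    def test_recovers_halo_ridge_radius(self):
        size, center = 64, 32
        img = radial_field(size, center, ridge_profile)
        mask = disk_mask(size, center, 10)
        out = halo_correct(img, mask, HaloCorrectionConfig(max_iterations=20, direction="grow"))
        # independent oracle: the radial argmax of the profile
        radii = np.linspace(0, 30, 3001)
        ridge = radii[np.argmax(ridge_profile(radii))]
        assert ridge == pytest.approx(14.0, abs=0.01)
        pts = extract_contours(out)
        mean_radius = np.mean([np.hypot(p[0] - center, p[1] - center) for p in pts])
        assert abs(mean_radius - ridge) <= 1.0

    def test_iteration_cap_on_monotone_ramp(self):
        img = np.tile(np.arange(30, dtype=float), (10, 1))
        mask = np.zeros((10, 30), dtype=np.uint8)
        mask[:, :3] = 1
        res = halo_correct_result(img, mask, HaloCorrectionConfig(max_iterations=3, direction="grow"))
        assert res.iterations == 3
        assert not res.converged
        assert res.mask[:, :6].all() and not res.mask[:, 6:].any()

    def test_growth_only_and_band_bounded(self, rng):
        from scipy import ndimage

        for _ in range(5):
            img = rng.uniform(0, 255, size=(24, 24))
            mask = (rng.uniform(size=(24, 24)) > 0.7).astype(np.uint8)
            cap = 4
            out = halo_correct(img, mask, HaloCorrectionConfig(max_iterations=cap, direction="grow"))
            assert np.all(out >= mask)
            allowed = ndimage.binary_dilation(mask, np.ones((3, 3)), iterations=cap)
            assert not np.any(out & ~allowed)

    def test_terminates_within_cap_on_random_inputs(self, rng):
        for _ in range(20):
            img = rng.uniform(0, 255, size=(16, 16))
            mask = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
            res = halo_correct_result(img, mask, HaloCorrectionConfig(max_iterations=7, direction="grow"))
            assert res.iterations <= 7

    def test_idempotent_at_fixed_point(self, rng):
        img = rng.uniform(0, 255, size=(20, 20))
        mask = (rng.uniform(size=(20, 20)) > 0.6).astype(np.uint8)
        cfg = HaloCorrectionConfig(max_iterations=50, direction="grow")
        first = halo_correct_result(img, mask, cfg)
        assert first.converged
        second = halo_correct_result(img, first.mask, cfg)
        np.testing.assert_array_equal(second.mask, first.mask)


class TestHaloCorrectShrink:
    def test_peels_back_to_ridge(self):
        size, center = 64, 32
        img = radial_field(size, center, ridge_profile)
        mask = disk_mask(size, center, 18)  # over-covers the ridge at r=14
        # the gradient margin must exceed the intra-layer intensity spread of
        # the discretized ramp (slope x ~0.5 px), else same-layer neighbors
        # keep the peel rolling past the ridge
        cfg = HaloCorrectionConfig(max_iterations=20, direction="shrink", gradient_epsilon=6.0)
        res = halo_correct_result(img, mask, cfg)
        assert res.converged
        pts = extract_contours(res.mask)
        mean_radius = np.mean([np.hypot(p[0] - center, p[1] - center) for p in pts])
        assert abs(mean_radius - 14.0) <= 1.0

    def test_shrink_only_removes_pixels(self, rng):
        img = rng.uniform(0, 255, size=(20, 20))
        mask = (rng.uniform(size=(20, 20)) > 0.4).astype(np.uint8)
        out = halo_correct(img, mask, HaloCorrectionConfig(direction="shrink"))
        assert np.all(out <= mask)

    def test_stable_when_interior_darker(self):
        # left block on a horizontal ramp: every interior neighbor of the
        # contour column is dimmer or equal, so nothing peels
        img = np.tile(10.0 * np.arange(30), (12, 1))
        mask = np.zeros((12, 30), dtype=np.uint8)
        mask[:, :11] = 1
        res = halo_correct_result(img, mask, HaloCorrectionConfig(direction="shrink"))
        np.testing.assert_array_equal(res.mask, mask)
        assert res.converged and res.iterations == 0


class TestValidation:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            halo_correct(np.zeros((5, 5)), np.zeros((6, 6), dtype=np.uint8))

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            HaloCorrectionConfig(direction="sideways")

    def test_bad_iterations_rejected(self):
        with pytest.raises(ValueError):
            HaloCorrectionConfig(max_iterations=0)
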