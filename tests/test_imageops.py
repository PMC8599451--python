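"""Raster primitives: HSB gating, filters, thresholds, skeleton topology.

The automatic thresholds are checked against exhaustive 256-candidate
brute-force evaluations of each published criterion, written here as
plain double loops independent of the implementation.
"""

import numpy as np
import pytest

from cardioquant.imageops import (
    BinaryMask,
    HSBRange,
    SectionImage,
    auto_threshold,
    despeckle,
    gaussian_blur,
    hsb255_to_rgb,
    hsb_threshold,
    median_filter,
    rolling_ball_subtract,
    skeleton_stats,
    unsharp_mask,
)

# ---------------------------------------------------------------------------
# brute-force threshold oracles (256 candidates each)


def brute_isodata_ok(hist, t):
    """Fixed-point check: t equals the rounded intermean of its split."""
    levels = np.arange(256)
    below, above = hist[: t + 1], hist[t + 1 :]
    if below.sum() == 0 or above.sum() == 0:
        return False
    mb = (levels[: t + 1] * below).sum() / below.sum()
    ma = (levels[t + 1 :] * above).sum() / above.sum()
    return t == int(round((mb + ma) / 2.0))


def brute_yen(hist):
    p = hist / hist.sum()
    best_t, best = None, -np.inf
    for t in range(256):
        p1 = p[: t + 1].sum()
        if hist[: t + 1].sum() == 0 or hist[t + 1 :].sum() == 0:
            continue
        p1sq = (p[: t + 1] ** 2).sum()
        p2sq = (p[t + 1 :] ** 2).sum()
        crit = -np.log(max(p1sq * p2sq, 1e-300)) + 2 * np.log(
            max(p1 * (1 - p1), 1e-300)
        )
        if crit > best:
            best, best_t = crit, t
    return best_t


def brute_triangle(hist):
    nz = np.nonzero(hist)[0]
    peak = int(np.argmax(hist))
    flipped = (peak - nz[0]) > (nz[-1] - peak)
    h = hist[::-1] if flipped else hist
    peak = 255 - peak if flipped else peak
    end = 255 - nz[0] if flipped else nz[-1]
    # maximize perpendicular distance from (b, h[b]) to the peak-end line
    x1, y1, x2, y2 = peak, h[peak], end, 0.0
    norm = np.hypot(y2 - y1, x2 - x1)
    best_t, best = peak, -np.inf
    for b in range(peak, end + 1):
        dist = abs((y2 - y1) * b - (x2 - x1) * h[b] + x2 * y1 - y2 * x1) / norm
        if h[b] <= y1 + (y2 - y1) * (b - x1) / (x2 - x1) and dist > best:
            best, best_t = dist, b
    return 255 - best_t if flipped else best_t


def brute_moments(hist):
    """p0 from the moment-preservation equations (solved via np.roots),
    then the candidate whose cumulative fraction is closest to p0."""
    p = hist / hist.sum()
    lv = np.arange(256.0)
    m1, m2, m3 = (p * lv).sum(), (p * lv**2).sum(), (p * lv**3).sum()
    cd = m2 - m1**2
    c0 = (-m2**2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    z = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z[1] - m1) / (z[1] - z[0])
    cum = np.cumsum(p)
    return int(np.argmin([abs(cum[t] - p0) for t in range(256)]))


def _random_bimodal(rng):
    a = rng.normal(rng.uniform(40, 90), rng.uniform(5, 25), (64, 64))
    b = rng.normal(rng.uniform(150, 220), rng.uniform(5, 25), (64, 64))
    sel = rng.random((64, 64)) < rng.uniform(0.3, 0.7)
    return np.clip(np.where(sel, a, b), 0, 255).astype(np.uint8)


class TestAutoThreshold:
    def test_methods_match_brute_force_on_random_images(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            img = _random_bimodal(rng)
            hist = np.bincount(img.ravel(), minlength=256).astype(float)
            _, t_iso = auto_threshold(img, "default_isodata")
            assert brute_isodata_ok(hist, t_iso)
            _, t_yen = auto_threshold(img, "yen")
            assert t_yen == brute_yen(hist)
            _, t_tri = auto_threshold(img, "triangle")
            assert t_tri == brute_triangle(hist)
            _, t_mom = auto_threshold(img, "moments")
            assert t_mom == brute_moments(hist)

    def test_two_level_image_separated_exactly(self):
        img = np.where(np.arange(4096).reshape(64, 64) % 3 == 0, 20, 220).astype(
            np.uint8
        )
        for method in ("default_isodata", "yen", "triangle", "moments"):
            mask, t = auto_threshold(img, method)
            assert 20 <= t < 220
            assert np.array_equal(mask.data, img == 220)

    def test_bimodal_mixture_thresholds_fall_between_modes(self):
        rng = np.random.default_rng(5)
        n = 64 * 64
        sel = rng.random(n) < 0.5
        img = (
            np.clip(np.where(sel, rng.normal(50, 10, n), rng.normal(200, 10, n)), 0, 255)
            .astype(np.uint8)
            .reshape(64, 64)
        )
        for method in ("default_isodata", "yen", "triangle", "moments"):
            mask, t = auto_threshold(img, method)
            assert 50 < t < 200
            # essentially perfect separation of the two populations
            err = (mask.data.ravel() != ~sel).mean()
            assert err < 0.02

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            auto_threshold(np.full((16, 16), 7, dtype=np.uint8), "yen")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            auto_threshold(np.zeros((4, 4), dtype=np.uint8), "otsu")


class TestHSBGate:
    def test_inclusive_bounds(self):
        gate = HSBRange(140, 200, 10, 255, 0, 255)
        inside = hsb255_to_rgb(np.array([[[150, 128, 200]]], dtype=np.uint8))
        img = SectionImage(inside, 1.0)
        assert hsb_threshold(img, gate).data.all()
        # hue 139 is below the inclusive lower bound
        outside = hsb255_to_rgb(np.array([[[130, 128, 200]]], dtype=np.uint8))
        assert not hsb_threshold(SectionImage(outside, 1.0), gate).data.any()

    def test_widening_gate_is_monotone(self, rng):
        img = SectionImage(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8), 1.0)
        narrow = hsb_threshold(img, HSBRange(100, 150, 50, 200, 20, 230))
        wide = hsb_threshold(img, HSBRange(80, 170, 30, 220, 10, 250))
        assert (narrow.data <= wide.data).all()

    def test_wraparound_hue(self):
        red = hsb255_to_rgb(np.array([[[3, 200, 200]]], dtype=np.uint8))
        gate = HSBRange(240, 10, 10, 255, 0, 255)  # wraps through 0
        assert hsb_threshold(SectionImage(red, 1.0), gate).data.all()

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            hsb_threshold(SectionImage(np.zeros((8, 8), np.uint8), 1.0), HSBRange())


class TestFilters:
    def test_constant_image_flattened_by_rolling_ball(self):
        out = rolling_ball_subtract(np.full((64, 64), 100.0), 10)
        assert out.max() <= 1.0

    def test_rolling_ball_preserves_small_features(self):
        yy, xx = np.mgrid[:128, :128]
        background = 0.3 * xx  # smooth gradient, amplitude ~38
        img = background.copy()
        for cy, cx in [(30, 30), (64, 90), (100, 50)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 25] += 50
        out = rolling_ball_subtract(img, 50)
        for cy, cx in [(30, 30), (64, 90), (100, 50)]:
            assert out[cy, cx] == pytest.approx(50, rel=0.1)

    def test_rolling_ball_output_nonnegative(self, rng):
        out = rolling_ball_subtract(rng.uniform(0, 255, (64, 64)), 20)
        assert (out >= 0).all()

    def test_constant_images_pass_filters_unchanged(self):
        const = np.full((32, 32), 55.0)
        assert np.allclose(median_filter(const, 1), const)
        assert np.allclose(gaussian_blur(const, 5), const)
        assert np.allclose(unsharp_mask(const, 2, 0.6), const)

    def test_median_removes_single_pixel_impulse(self):
        img = np.zeros((21, 21))
        img[10, 10] = 255
        assert median_filter(img, 1).max() == 0

    def test_gaussian_preserves_mean(self, rng):
        img = rng.uniform(0, 255, (128, 128))
        out = gaussian_blur(img, 3)
        assert out.mean() == pytest.approx(img.mean(), rel=0.005)

    def test_unsharp_matches_closed_form(self, rng):
        yy, xx = np.mgrid[:64, :64]
        img = 0.5 * xx + 20 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 50.0)
        out = unsharp_mask(img, 2, 0.60)
        expected = (img - 0.60 * gaussian_blur(img, 2)) / 0.40
        assert np.allclose(out, expected)

    def test_despeckle_removes_isolated_pixels(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[5, 5] = True
        mask[10:15, 10:15] = True
        out = despeckle(mask)
        assert not out[5, 5]
        assert out[12, 12]

    def test_invalid_radius_rejected(self):
        for func, arg in [(rolling_ball_subtract, 0), (median_filter, 0),
                          (gaussian_blur, -1)]:
            with pytest.raises(ValueError):
                func(np.zeros((8, 8)), arg)

    def test_filters_commute_with_translation(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        shifted = np.roll(img, 7, axis=1)
        out_a = np.roll(gaussian_blur(img, 2), 7, axis=1)
        out_b = gaussian_blur(shifted, 2)
        # compare away from the wrap border
        assert np.allclose(out_a[:, 16:48], out_b[:, 16:48], atol=1e-6)


class TestSkeleton:
    def test_straight_bar_is_one_branch(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[15:18, 4:28] = True
        _, branches, junctions = skeleton_stats(BinaryMask(mask, 1.0))
        assert (branches, junctions) == (1, 0)

    def test_plus_sign_has_four_branches_one_junction(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[19:22, 4:37] = True
        mask[4:37, 19:22] = True
        _, branches, junctions = skeleton_stats(BinaryMask(mask, 1.0))
        assert junctions == 1
        assert branches == 4

    def test_grid_pattern_topology(self):
        """2x2 grid of connected segments, counted by hand.

        Of the 3x3 crossings, the 4 corners have degree 2 (not
        junctions); the 4 edge-middles and the center have degree >= 3,
        giving 5 junctions. Removing them splits the lattice into the 4
        corner L-pieces of the outer ring plus the 4 inner cross arms:
        8 branches.
        """
        mask = np.zeros((61, 61), dtype=bool)
        for pos in (10, 30, 50):
            mask[pos - 1 : pos + 2, 9:52] = True
            mask[9:52, pos - 1 : pos + 2] = True
        _, branches, junctions = skeleton_stats(BinaryMask(mask, 1.0))
        assert junctions == 5
        assert branches == 8

    def test_empty_mask_gives_zeros(self):
        _, branches, junctions = skeleton_stats(
            BinaryMask(np.zeros((8, 8), dtype=bool), 1.0)
        )
        assert (branches, junctions) == (0, 0)
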