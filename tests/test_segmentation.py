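"""Normalization, rolling-ball background, thresholding and mask import."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

import clearquant as cq
from skimage.morphology import disk

from conftest import make_stack


def naive_rolling_ball(plane, radius):
    """Exhaustive sliding-ball oracle: min then max over the disk neighborhood."""
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    ny, nx = plane.shape

    def scan(img, fn):
        out = np.empty_like(img)
        for y in range(ny):
            for x in range(nx):
                vals = [
                    img[y + dy, x + dx]
                    for dy, dx in offsets
                    if 0 <= y + dy < ny and 0 <= x + dx < nx
                ]
                out[y, x] = fn(vals)
        return out

    return scan(scan(plane, min), max)


class TestNormalizeStack:
    def test_full_range_percentiles_map_to_unit_interval(self):
        stack = make_stack(np.arange(101.0).reshape(101, 1, 1))
        out = cq.normalize_stack(stack, low_pct=0, high_pct=100)
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0
        np.testing.assert_allclose(out.voxels[:, 0, 0], np.arange(101) / 100)

    def test_constant_stack_warns_and_returns_zeros(self):
        stack = make_stack(np.full((4, 4, 4), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            out = cq.normalize_stack(stack)
        assert not out.voxels.any()

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_to_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 3, (5, 8, 8))
        base = cq.normalize_stack(make_stack(v), 1, 99).voxels
        trans = cq.normalize_stack(make_stack(a * v + b), 1, 99).voxels
        np.testing.assert_allclose(base, trans, atol=1e-9)

    def test_normalized_intensities_in_unit_interval(self):
        rng = np.random.default_rng(1)
        out = cq.normalize_stack(make_stack(rng.normal(size=(6, 9, 9))))
        assert out.voxels.min() >= 0 and out.voxels.max() <= 1


class TestRollingBallBackground:
    def test_constant_plane_is_its_own_background(self):
        plane = np.full((12, 12), 3.5)
        bg = cq.rolling_ball_background(plane, 3)
        np.testing.assert_array_equal(bg, plane)

    def test_isolated_peak_removed(self):
        plane = np.zeros((11, 11))
        plane[5, 5] = 10.0
        assert not cq.rolling_ball_background(plane, 3).any()

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_naive_sliding_ball_oracle(self, radius):
        rng = np.random.default_rng(radius)
        plane = rng.uniform(0, 100, (16, 16))
        np.testing.assert_allclose(
            cq.rolling_ball_background(plane, radius),
            naive_rolling_ball(plane, radius),
        )

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(5)
        plane = rng.uniform(0, 10, (20, 20))
        bg = cq.rolling_ball_background(plane, 2)
        assert np.all(bg <= plane + 1e-12)
        np.testing.assert_allclose(cq.rolling_ball_background(bg, 2), bg)

    def test_radius_larger_than_both_dims_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cq.rolling_ball_background(np.zeros((4, 4)), 10)

    def test_paraboloid_variant_runs(self):
        rng = np.random.default_rng(6)
        plane = rng.uniform(0, 10, (16, 16))
        bg = cq.rolling_ball_background(plane, 3, method="paraboloid")
        assert np.all(bg <= plane + 1e-9)


class TestSubtractBackground:
    def test_flat_stack_subtracts_to_zero(self):
        out = cq.subtract_background(make_stack(np.full((3, 10, 10), 4.0)), 2)
        assert not out.voxels.any()

    def test_small_peak_height_preserved(self):
        v = np.full((1, 15, 15), 2.0)
        v[0, 7, 7] = 9.0
        out = cq.subtract_background(make_stack(v), 3)
        assert out.voxels[0, 7, 7] == pytest.approx(7.0)

    def test_never_increases_any_voxel(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 50, (4, 16, 16))
        out = cq.subtract_background(make_stack(v), 2)
        assert np.all(out.voxels <= v + 1e-12)


def otsu_variance_by_cut(values):
    """Between-class variance of every one of the 256 histogram bin cuts.

    Returns (bin upper-class-start centers, variances): cut k puts bins < k
    in the lower class. Exhaustive oracle for Otsu's criterion.
    """
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    cuts, variances = [], []
    for k in range(1, 256):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        cuts.append(centers[k - 1])
        variances.append(w0 * w1 * (mu0 - mu1) ** 2)
    return np.array(cuts), np.array(variances)


class TestThresholdMask:
    def test_fixed_requires_value(self):
        with pytest.raises(ValueError, match="value"):
            cq.threshold_mask(make_stack(np.zeros((2, 2, 2))), method="fixed")

    def test_all_below_threshold_gives_empty_mask(self):
        mask = cq.threshold_mask(make_stack(np.full((2, 3, 3), 0.1)),
                                 method="fixed", value=0.5)
        assert not mask.voxels.any()

    def test_two_level_stack_selects_upper_level_exactly(self):
        rng = np.random.default_rng(3)
        v = np.where(rng.random((4, 8, 8)) < 0.3, 0.8, 0.2)
        mask = cq.threshold_mask(make_stack(v), method="fixed", value=0.5)
        np.testing.assert_array_equal(mask.voxels, v == 0.8)
        assert mask.threshold_used == 0.5

    def test_otsu_in_intermode_gap_and_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        lo = rng.normal(0.2, 0.02, 3000)
        hi = rng.normal(0.8, 0.02, 1000)
        v = np.concatenate([lo, hi])
        stack = make_stack(np.clip(v, 0, 1).reshape(10, 20, 20))
        mask = cq.threshold_mask(stack, method="otsu")
        t = mask.threshold_used
        # the threshold lies in the gap: it cleanly separates the two modes
        assert (lo < t).mean() > 0.99 and (hi > t).mean() > 0.99
        # and it attains the exhaustive between-class variance maximum
        # (ties across the empty gap bins are equivalent maximizers)
        cuts, variances = otsu_variance_by_cut(stack.voxels.ravel())
        var_at_t = variances[np.argmin(np.abs(cuts - t))]
        assert var_at_t >= (1 - 1e-9) * variances.max()

    def test_mask_count_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(8)
        stack = make_stack(rng.random((5, 12, 12)))
        counts = [
            cq.threshold_mask(stack, method="fixed", value=t).voxels.sum()
            for t in np.linspace(0.05, 0.95, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestImportMask(object):
    def test_binary_file_roundtrip_identical(self, tmp_path, small_scene):
        path = tmp_path / "mask.tif"
        tifffile.imwrite(path, small_scene.truth_mask.astype(np.uint8))
        mask = cq.import_mask(path)
        np.testing.assert_array_equal(mask.voxels, small_scene.truth_mask)
        assert mask.source == "imported"

    def test_binary_file_ignores_prob_threshold(self, tmp_path):
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, (np.arange(8).reshape(2, 2, 2) % 2 * 255).astype(np.uint8))
        a = cq.import_mask(path, prob_threshold=0.1).voxels
        b = cq.import_mask(path, prob_threshold=0.9).voxels
        np.testing.assert_array_equal(a, b)

    def test_probability_half_everywhere_is_empty_at_default(self, tmp_path):
        path = tmp_path / "p.tif"
        tifffile.imwrite(path, np.full((3, 4, 4), 0.5, dtype=np.float32))
        assert not cq.import_mask(path).voxels.any()  # strict inequality

    def test_probabilities_outside_unit_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.tif"
        tifffile.imwrite(path, np.full((2, 4, 4), 1.5, dtype=np.float32))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cq.import_mask(path)

    def test_multichannel_file_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.random.default_rng(0).random((2, 4, 4, 3)).astype(np.float32))
        with pytest.raises(ValueError, match="single-channel"):
            cq.import_mask(path)


class TestInternalSegmentationPath:
    def test_recovers_truth_mask_where_signal_strong(self, noise_free):
        # noise-free rendered scene, amplitude >> background: above the
        # half-depth the internal path should match the truth almost exactly.
        scene = cq.make_scene(cq.SceneParams(shape=(32, 32, 100), seed=13))
        model = cq.AttenuationModel(kind="sigmoid", d_half_um=250.0)
        noise = cq.NoiseParams(background_level=1.0, gaussian_sd=0.0)
        stack = cq.render_stack(scene, model, noise, seed=0, amplitude=100.0)
        mask = cq.segment_stack(stack, radius_px=5, method="fixed", value=0.2)
        strong = cq.attenuation_profile(model, stack.depths_um) > 0.5
        m, t = mask.voxels[strong], scene.truth_mask[strong]
        jaccard = (m & t).sum() / (m | t).sum()
        assert jaccard >= 0.9
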