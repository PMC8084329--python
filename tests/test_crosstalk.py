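import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mbiclean import (
    ChannelImage,
    ChannelLookupError,
    CrosstalkParams,
    DegenerateInputWarning,
    DimensionError,
    binarize,
    build_contaminant_mask,
    cap_counts,
    gaussian_blur,
    intensity_histogram,
    remove_crosstalk,
    rescale_max1,
    subtract_masked,
)
from helpers import blur_brute

count_images = hnp.arrays(
    np.uint32, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=12),
    elements=st.integers(0, 50),
)


class TestCapCounts:
    def test_clips_at_cap(self):
        img = ChannelImage("h", np.array([[0, 3], [7, 2]], np.uint32))
        capped = cap_counts(img, 3)
        np.testing.assert_array_equal(capped.counts, [[0, 3], [3, 2]])
        assert capped.name == "h"

    def test_cap_above_max_is_identity(self, rng):
        arr = rng.poisson(2.0, (8, 8)).astype(np.uint32)
        np.testing.assert_array_equal(cap_counts(arr, arr.max() + 1), arr)

    def test_matches_elementwise_oracle(self, rng):
        arr = rng.poisson(1.0, (16, 16)).astype(np.uint32)
        capped = cap_counts(arr, 2)
        for i in range(16):
            for j in range(16):
                assert capped[i, j] == min(arr[i, j], 2)
        assert capped.dtype == arr.dtype

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            cap_counts(np.ones((2, 2)), 0)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self, rng):
        arr = rng.poisson(1.0, (6, 6)).astype(np.uint32)
        np.testing.assert_array_equal(gaussian_blur(arr, 0), arr)

    def test_impulse_matches_kernel_evaluation(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        blurred = gaussian_blur(img, 1.0)
        # center value is the kernel's central weight 1/(2*pi*sigma^2)
        assert blurred[7, 7] == pytest.approx(1.0 / (2.0 * np.pi), abs=1e-12)
        np.testing.assert_allclose(blurred, blur_brute(img, 1.0), atol=1e-12)
        # grid sum equals the truncated kernel mass (<1, not renormalized)
        kernel_mass = blur_brute(img, 1.0).sum()
        assert blurred.sum() == pytest.approx(kernel_mass, abs=1e-12)
        assert kernel_mass < 1.0

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_matches_bruteforce_on_random_image(self, rng, sigma):
        arr = rng.poisson(2.0, (10, 10)).astype(float)
        np.testing.assert_allclose(gaussian_blur(arr, sigma), blur_brute(arr, sigma), atol=1e-9)

    def test_constant_image_interior_limit(self):
        arr = np.full((21, 21), 5.0)
        blurred = gaussian_blur(arr, 1.0)
        impulse = np.zeros((15, 15))
        impulse[7, 7] = 1.0
        mass = blur_brute(impulse, 1.0).sum()  # truncated kernel mass
        assert blurred[10, 10] == pytest.approx(5.0 * mass, abs=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.ones((3, 3)), -0.1)


class TestRescaleBinarize:
    def test_rescale_known_values(self):
        np.testing.assert_allclose(
            rescale_max1(np.array([[0.0, 2.0], [4.0, 1.0]])), [[0, 0.5], [1, 0.25]]
        )

    def test_rescale_all_zero_warns(self):
        with pytest.warns(DegenerateInputWarning):
            out = rescale_max1(np.zeros((3, 3)))
        np.testing.assert_array_equal(out, 0)

    @given(count_images)
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_rescale_max_is_one_and_ratios_preserved(self, arr):
        if arr.max() == 0:
            return
        out = rescale_max1(arr)
        assert out.max() == 1.0
        np.testing.assert_allclose(out * arr.max(), arr, atol=1e-9)

    def test_binarize_known_and_boundary(self):
        np.testing.assert_array_equal(
            binarize(np.array([[0.0, 0.5], [1.0, 0.2]]), 0.5), [[0, 1], [1, 0]]
        )
        np.testing.assert_array_equal(binarize(np.zeros((2, 2)), 0.0), 1)

    def test_binarize_matches_loop_oracle(self, rng):
        arr = rng.uniform(0, 1, (9, 9))
        mask = binarize(arr, 0.3)
        for i in range(9):
            for j in range(9):
                assert mask[i, j] == (1 if arr[i, j] >= 0.3 else 0)

    def test_binarize_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.5)


class TestContaminantMask:
    def test_composition_order(self, rng):
        """Mask equals the explicit cap -> blur -> rescale -> binarize chain."""
        src = rng.poisson(2.0, (8, 8)).astype(np.uint32)
        src[2:4, 2:4] = 5
        expected = binarize(rescale_max1(gaussian_blur(np.minimum(src, 5), 1.0)), 0.2)
        np.testing.assert_array_equal(build_contaminant_mask(src, 5, 1.0, 0.2), expected)

    def test_sigma_zero_single_pixel(self):
        src = np.zeros((9, 9), np.uint32)
        src[4, 4] = 10
        mask = build_contaminant_mask(src, 3, 0.0, 0.5)
        assert mask[4, 4] == 1 and mask.sum() == 1

    def test_all_zero_source_warns(self):
        with pytest.warns(DegenerateInputWarning):
            mask = build_contaminant_mask(np.zeros((5, 5), np.uint32), 3, 1.0, 0.5)
        assert mask.sum() == 0


class TestIntensityHistogram:
    def test_known_cases(self):
        hist = intensity_histogram(np.zeros((4, 4)), 10)
        assert hist.counts[0] == 16 and hist.counts[1:].sum() == 0
        hist = intensity_histogram(np.array([[0.0, 1.0]]), 2)
        np.testing.assert_array_equal(hist.counts, [1, 1])  # 1.0 lands in the last bin

    def test_conserves_pixel_count(self, rng):
        arr = rng.uniform(0, 1, (13, 7))
        assert intensity_histogram(arr, 17).counts.sum() == arr.size


class TestSubtractMasked:
    def test_known_values_with_clipping(self):
        out = subtract_masked(np.array([[2, 5]], np.uint32), np.array([[1, 1]]), 3)
        np.testing.assert_array_equal(out, [[0, 2]])

    def test_zero_removal_is_identity(self, rng):
        arr = rng.poisson(3.0, (8, 8)).astype(np.uint32)
        mask = rng.integers(0, 2, (8, 8))
        np.testing.assert_array_equal(subtract_masked(arr, mask, 0), arr)

    def test_huge_value_zeroes_only_masked_pixels(self, rng):
        arr = rng.poisson(3.0, (12, 12)).astype(np.uint32)
        mask = rng.integers(0, 2, (12, 12))
        out = subtract_masked(arr, mask, 10**9)
        assert (out[mask == 1] == 0).all()
        np.testing.assert_array_equal(out[mask == 0], arr[mask == 0])

    def test_fractional_value_gives_float(self):
        out = subtract_masked(np.array([[3]], np.uint32), np.array([[1]]), 0.5)
        assert out.dtype.kind == "f" and out[0, 0] == 2.5

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            subtract_masked(np.ones((2, 2), np.uint32), np.ones((3, 3)), 1)


def _phantom_stack(small_phantom):
    return small_phantom.stack


class TestRemoveCrosstalk:
    def params(self, **kw):
        base = dict(source="source", targets=["target"], cap=3, sigma=1.0, threshold=0.2, remove_value=2)
        base.update(kw)
        return CrosstalkParams(**base)

    def test_empty_targets_identity(self, small_phantom):
        cleaned, _ = remove_crosstalk(small_phantom.stack, self.params(targets=[]))
        for a, b in zip(cleaned, small_phantom.stack):
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_unknown_channel_lists_available(self, small_phantom):
        with pytest.raises(ChannelLookupError, match="available"):
            remove_crosstalk(small_phantom.stack, self.params(targets=["nope"]))

    def test_source_is_never_its_own_target(self):
        with pytest.raises(ValueError):
            self.params(targets=["source"])

    def test_equals_manual_component_chain(self, small_phantom):
        p = self.params()
        cleaned, log = remove_crosstalk(small_phantom.stack, p)
        mask = build_contaminant_mask(small_phantom.source, p.cap, p.sigma, p.threshold)
        manual = subtract_masked(small_phantom.target, mask, p.remove_value)
        np.testing.assert_array_equal(cleaned.get("target").counts, manual.counts)
        np.testing.assert_array_equal(
            cleaned.get("source").counts, small_phantom.source.counts
        )
        assert log.stage == "crosstalk" and log.parameters["rules"][0]["cap"] == 3

    def test_conservation_and_locality(self, small_phantom):
        p = self.params()
        cleaned, _ = remove_crosstalk(small_phantom.stack, p)
        before = small_phantom.target.counts
        after = cleaned.get("target").counts
        assert (after <= before).all() and (after >= 0).all()
        mask = build_contaminant_mask(small_phantom.source, p.cap, p.sigma, p.threshold)
        np.testing.assert_array_equal(after[mask == 0], before[mask == 0])

    def test_monotone_in_threshold(self, small_phantom):
        outs = [
            remove_crosstalk(small_phantom.stack, self.params(threshold=t))[0].get("target").counts
            for t in (0.1, 0.4, 0.8)
        ]
        assert (outs[0] <= outs[1]).all() and (outs[1] <= outs[2]).all()

    def test_monotone_in_remove_value(self, small_phantom):
        outs = [
            remove_crosstalk(small_phantom.stack, self.params(remove_value=v))[0].get("target").counts
            for v in (1, 3, 10)
        ]
        assert (outs[1] <= outs[0]).all() and (outs[2] <= outs[1]).all()

    def test_repeated_application_monotone_decrease(self, small_phantom):
        p = self.params()
        once, _ = remove_crosstalk(small_phantom.stack, p)
        twice, _ = remove_crosstalk(once, p)
        a, b = once.get("target").counts, twice.get("target").counts
        assert (b <= a).all()
        mask = build_contaminant_mask(small_phantom.source, p.cap, p.sigma, p.threshold)
        changed = a != b
        assert (mask[changed] == 1).all() and (a[changed] >= 1).all()

    def test_phantom_restoration_with_zero_out(self):
        """With a mask matching the source support exactly and an arbitrarily
        large remove value, every contaminated pixel returns to its clean
        value when the target has no structure of its own there."""
        from mbiclean import PhantomSpec, generate_phantom

        ph = generate_phantom(
            PhantomSpec(height=128, width=128, n_cells=6, noise_rate=0.0,
                        n_aggregates=0, crosstalk_fraction=0.5, seed=3)
        )
        contaminated = ph.truth["target"]["contamination"] > 0
        assert contaminated.sum() > 100
        cleaned, _ = remove_crosstalk(
            ph.stack,
            CrosstalkParams(source="source", targets=["target"], cap=1,
                            sigma=0.0, threshold=0.5, remove_value=10**6),
        )
        restored = cleaned.get("target").counts[contaminated] == ph.clean("target")[contaminated]
        assert restored.mean() >= 0.99
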