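"""Bicubic kernel/resampling oracles, augmentation rules and split behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slenet.cytosim import DatasetManifest
from slenet.preprocess import (
    AugmentConfig,
    BicubicKernelParams,
    SplitRatios,
    augment_image,
    bicubic_weight,
    photometric_adjust,
    resize_bicubic,
    split_manifest,
    split_sizes,
)


def brute_force_resize(img, target, a):
    """Literal 4x4-neighbourhood double sum with clamped edges."""
    h, w, c = img.shape
    th, tw = target
    out = np.zeros((th, tw, c))
    for i in range(th):
        sy = (i + 0.5) * h / th - 0.5
        by = int(np.floor(sy))
        for j in range(tw):
            sx = (j + 0.5) * w / tw - 0.5
            bx = int(np.floor(sx))
            acc = np.zeros(c)
            for ky in range(by - 1, by + 3):
                for kx in range(bx - 1, bx + 3):
                    wgt = bicubic_weight(sy - ky, a) * bicubic_weight(sx - kx, a)
                    acc += wgt * img[min(max(ky, 0), h - 1), min(max(kx, 0), w - 1)]
            out[i, j] = acc
    return np.clip(out, 0, 255)


class TestBicubicWeight:
    def test_hand_evaluated_values_at_keys_constant(self):
        assert bicubic_weight(0.0) == pytest.approx(1.0, abs=1e-15)
        assert bicubic_weight(1.0) == pytest.approx(0.0, abs=1e-15)
        assert bicubic_weight(1.5) == pytest.approx(-0.0625, abs=1e-15)
        assert bicubic_weight(2.5) == 0.0
        assert bicubic_weight(-1.5) == pytest.approx(-0.0625, abs=1e-15)

    def test_near_branch_formula_for_a_equal_one(self):
        a = 1.0
        x = 0.6
        assert bicubic_weight(x, a) == pytest.approx(
            (a + 2) * x**3 - (a + 3) * x**2 + 1, abs=1e-15
        )

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.0, 1.0, exclude_max=True))
    def test_partition_of_unity(self, t):
        total = sum(bicubic_weight(t - k) for k in (-1, 0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_kernel_constant_rejected(self):
        with pytest.raises(ValueError):
            BicubicKernelParams(a=0.3)


class TestResize:
    @pytest.mark.parametrize("a", [-0.5, 1.0])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_double_sum(self, a, seed):
        img = np.random.default_rng(seed).uniform(0, 255, (16, 16, 3))
        got = resize_bicubic(img, (8, 8), BicubicKernelParams(a))
        np.testing.assert_allclose(got, brute_force_resize(img, (8, 8), a), atol=1e-6)

    def test_constant_image_is_preserved(self):
        img = np.full((448, 448, 3), 91.0)
        out = resize_bicubic(img, (224, 224))
        np.testing.assert_allclose(out, 91.0, atol=1e-9)

    def test_same_size_resize_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 255, (224, 224, 3))
        np.testing.assert_allclose(resize_bicubic(img, (224, 224)), img, atol=1e-9)

    def test_grayscale_input_supported(self):
        img = np.random.default_rng(0).uniform(0, 255, (16, 16))
        assert resize_bicubic(img, (8, 8)).shape == (8, 8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            resize_bicubic(np.zeros((3, 10, 3)), (8, 8))


class TestAugment:
    def test_identity_configuration_returns_input(self):
        img = np.random.default_rng(0).uniform(0, 255, (20, 20, 3))
        out = augment_image(img, AugmentConfig.identity(), np.random.default_rng(1))
        np.testing.assert_array_equal(out, img)

    def test_brightness_rule_on_constant_image(self):
        img = np.full((8, 8, 3), 100.0)
        np.testing.assert_allclose(photometric_adjust(img, brightness=1.15), 115.0)

    def test_contrast_leaves_constant_image_unchanged(self):
        img = np.full((8, 8, 3), 77.0)
        np.testing.assert_allclose(photometric_adjust(img, contrast=1.1), 77.0, atol=1e-4)

    def test_contrast_stretches_about_channel_mean(self):
        img = np.zeros((1, 2, 1))
        img[0, 0, 0], img[0, 1, 0] = 40.0, 60.0
        out = photometric_adjust(img, contrast=1.1)
        np.testing.assert_allclose(out[:, :, 0], [[39.0, 61.0]], atol=1e-5)

    def test_output_stays_in_pixel_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (16, 16, 3))
        for _ in range(20):
            out = augment_image(img, AugmentConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 255.0

    def test_draws_are_reproducible_per_seed(self):
        img = np.random.default_rng(0).uniform(0, 255, (16, 16, 3))
        a = augment_image(img, AugmentConfig(), np.random.default_rng(42))
        b = augment_image(img, AugmentConfig(), np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(brightness_max_frac=1.5)
        with pytest.raises(ValueError):
            AugmentConfig(rotation_set=(45,))


def _manifest(n):
    return DatasetManifest(
        pd.DataFrame(
            {
                "path": [f"img_{i}.png" for i in range(n)],
                "stage": ["P", "E", "M", "D"] * (n // 4) + ["P"] * (n % 4),
                "split": ["unassigned"] * n,
            }
        )
    )


class TestSplit:
    def test_published_dataset_size_splits_to_printed_counts(self):
        m = split_manifest(_manifest(2655), SplitRatios(0.6, 0.2, 0.2), seed=0)
        sizes = m.frame["split"].value_counts()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (1593, 531, 531)

    def test_exact_division(self):
        assert split_sizes(10, SplitRatios(0.6, 0.2, 0.2)) == (6, 2, 2)

    def test_all_to_train_boundary(self):
        m = split_manifest(_manifest(9), SplitRatios(1.0, 0.0, 0.0), seed=3)
        assert (m.frame["split"] == "train").all()

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 5000))
    def test_sizes_partition_any_dataset(self, n):
        sizes = split_sizes(n, SplitRatios(0.6, 0.2, 0.2))
        assert sum(sizes) == n and min(sizes) >= 0

    def test_split_is_deterministic_and_exhaustive(self):
        a = split_manifest(_manifest(101), SplitRatios(), seed=9)
        b = split_manifest(_manifest(101), SplitRatios(), seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert set(a.frame["split"]) == {"train", "val", "test"}
        c = split_manifest(_manifest(101), SplitRatios(), seed=10)
        assert not a.frame["split"].equals(c.frame["split"])

    def test_invalid_ratios_and_preassigned_records_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitRatios(0.5, 0.2, 0.2)
        m = split_manifest(_manifest(10), SplitRatios(), seed=0)
        with pytest.raises(ValueError, match="unassigned"):
            split_manifest(m, SplitRatios(), seed=0)
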