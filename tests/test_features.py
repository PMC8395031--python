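"""Feature bank: registry, pooled stats, shape, GLCM, Laws, Gabor, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from dwirad.features import (
    GLCM_DESCRIPTORS,
    LAWS_1D,
    BankConfig,
    FeatureTable,
    extract_features,
    feature_names,
    gabor_features,
    gabor_kernel,
    glcm_features,
    glcm_matrix,
    haralick_descriptors,
    laws_bank,
    laws_features,
    parse_feature_name,
    pooled_statistics,
    shape_features,
    zscore_fit_apply,
)
from dwirad.imaging import ImageStack
from dwirad.segmentation import RoiSet, peritumoral_ring


def disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestRegistry:
    def test_counts_and_uniqueness(self):
        names = feature_names()
        assert len(names) == len(set(names)) == 2504
        by_cat = {}
        for n in names:
            cat = parse_feature_name(n)["category"]
            by_cat[cat] = by_cat.get(cat, 0) + 1
        assert by_cat == {
            "shape": 14,
            "firstorder": 30,
            "glcm": 270,
            "laws": 750,
            "gabor": 1440,
        }

    def test_per_channel_region_block_is_415(self):
        names = feature_names()
        block = [n for n in names if n.startswith("b800__intra__")]
        assert len(block) == 5 + 45 + 125 + 240 == 415

    def test_intra_peri_partition(self):
        names = feature_names()
        intra = [n for n in names if "__intra__" in n]
        peri = [n for n in names if "__peri__" in n]
        assert len(intra) == len(peri) == 1245
        assert 14 + len(intra) + len(peri) == 2504


class TestPooledStatistics:
    def test_symmetric_three_points(self):
        s = pooled_statistics(np.array([1.0, 2.0, 3.0]))
        assert s["mean"] == 2.0 and s["median"] == 2.0

    def test_constant_vector_degeneracy_rule(self):
        s = pooled_statistics(np.full(10, 4.2))
        assert s["sd"] == 0.0 and s["skewness"] == 0.0 and s["kurtosis"] == 0.0

    def test_matches_naive_moment_oracle(self, rng):
        v = rng.uniform(-3, 5, 50)
        s = pooled_statistics(v)
        n = len(v)
        mean = sum(v) / n
        m2 = sum((x - mean) ** 2 for x in v) / n
        m3 = sum((x - mean) ** 3 for x in v) / n
        m4 = sum((x - mean) ** 4 for x in v) / n
        assert s["mean"] == pytest.approx(mean, abs=1e-12)
        assert s["sd"] == pytest.approx(np.sqrt(m2), abs=1e-12)
        assert s["skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-10)
        assert s["kurtosis"] == pytest.approx(m4 / m2**2, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_statistics(np.array([]))


class TestShape:
    def test_area_is_pixel_count_times_spacing_squared(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True  # 100 px
        s = shape_features(mask, 1.328125)
        assert s["Area"] == pytest.approx(100 * 1.328125**2)

    def test_disk_circularity_and_reciprocal_identity(self):
        mask = disk((100, 100), (50, 50), 40)
        s = shape_features(mask, 1.0)
        assert 0.9 <= s["Circularity"] <= 1.1
        assert s["SphericalDisproportion"] * s["Sphericity"] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_box_filling_rectangle(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:25] = True
        s = shape_features(mask, 1.0)
        assert s["Extent"] == pytest.approx(1.0)
        assert s["Solidity"] == pytest.approx(1.0)

    def test_multi_component_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[12:15, 12:15] = True
        with pytest.raises(ValueError):
            shape_features(mask, 1.0)


class TestGlcm:
    def test_constant_image(self):
        img = np.full((10, 10), 7, dtype=int)
        d = haralick_descriptors(glcm_matrix(img, np.ones_like(img, bool), (0, 1)))
        assert d["Energy"] == pytest.approx(1.0)
        assert d["Contrast"] == pytest.approx(0.0)
        assert d["Entropy"] == pytest.approx(0.0)

    def test_checkerboard_contrast_one(self):
        yy, xx = np.mgrid[0:8, 0:8]
        img = (yy + xx) % 2
        d = haralick_descriptors(glcm_matrix(img, np.ones_like(img, bool), (0, 1)))
        assert d["Contrast"] == pytest.approx(1.0)

    def test_matrix_is_distribution(self, rng):
        img = rng.integers(0, 256, (16, 16))
        mask = disk((16, 16), (8, 8), 6)
        m = glcm_matrix(img, mask, (1, 1))
        assert (m >= 0).all()
        assert m.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        """Symmetric masked co-occurrence equals brute-force pair counting."""
        img = rng.integers(0, 8, (16, 16))
        mask = np.zeros((16, 16), bool)
        mask[2:14, 3:13] = True
        mask[5, 5] = False
        dr, dc = 1, -1
        counts = np.zeros((256, 256))
        for r in range(16):
            for c in range(16):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < 16 and 0 <= c2 < 16 and mask[r, c] and mask[r2, c2]:
                    counts[img[r, c], img[r2, c2]] += 1
        counts = counts + counts.T
        oracle = counts / counts.sum()
        np.testing.assert_allclose(glcm_matrix(img, mask, (dr, dc)), oracle, atol=1e-12)

    def test_feature_block_is_45(self, rng):
        img = rng.integers(0, 256, (24, 24))
        feats = glcm_features(img, np.ones((24, 24), bool))
        assert len(feats) == 45
        assert {f.split("__")[0] for f in feats} == set(GLCM_DESCRIPTORS)


class TestLaws:
    def test_kernel_sums(self):
        """L5L5 sums to 16^2; every filter with an E5/S5/R5 factor sums to 0.

        The wave kernel is used exactly as the feature table prints it,
        (-1 2 0 -2 -1), which sums to -2 — so W5-L5 combinations are not
        zero-sum.
        """
        bank = laws_bank()
        assert len(bank) == 25
        assert bank["L5L5"].sum() == 256  # (sum L5)^2 = 16^2
        sums_1d = {k: v.sum() for k, v in LAWS_1D.items()}
        for name, kernel in bank.items():
            expected = sums_1d[name[:2]] * sums_1d[name[2:]]
            assert kernel.sum() == pytest.approx(expected, abs=1e-12)
            if "E5" in name or "S5" in name or "R5" in name:
                assert kernel.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_sum_kernels_annihilate_constants(self):
        img = np.full((32, 32), 9.0)
        mask = disk((32, 32), (16, 16), 10)
        feats = laws_features(img, mask)
        nonzero_sum = {"L5L5", "L5W5", "W5L5", "W5W5"}
        for name, value in feats.items():
            if name.split("__")[0] not in nonzero_sum and name.endswith("__mean"):
                assert value == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive_convolution_oracle(self, rng):
        """E5S5 response at interior pixels equals a direct sliding-window
        dot product."""
        img = rng.normal(0, 1, (32, 32))
        mask = np.zeros((32, 32), bool)
        mask[10:22, 10:22] = True
        kernel = np.outer(LAWS_1D["E5"], LAWS_1D["S5"])
        oracle = np.zeros((32, 32))
        for r in range(2, 30):
            for c in range(2, 30):
                oracle[r, c] = np.sum(img[r - 2 : r + 3, c - 2 : c + 3] * kernel)
        feats = laws_features(img, mask)
        expected = pooled_statistics(np.abs(oracle[mask]))
        assert feats["E5S5__mean"] == pytest.approx(expected["mean"], abs=1e-9)
        assert feats["E5S5__sd"] == pytest.approx(expected["sd"], abs=1e-9)


class TestGabor:
    def test_dc_filter_orientation_invariant_passes_constants(self):
        img = np.full((48, 48), 5.0)
        mask = disk((48, 48), (24, 24), 10)
        bank = BankConfig(gabor_image_width=48)
        feats = gabor_features(img, mask, bank)
        dc_means = [v for k, v in feats.items() if k.startswith("f0-") and
                    k.endswith("__mean")]
        assert len(dc_means) == 8
        np.testing.assert_allclose(dc_means, 5.0, rtol=1e-9)

    def test_bank_size(self):
        img = np.random.default_rng(0).normal(0, 1, (32, 32))
        feats = gabor_features(img, np.ones((32, 32), bool),
                               BankConfig(gabor_image_width=32))
        assert len(feats) == 240  # 6 freqs x 8 orientations x 5 stats

    def test_matched_filter_peaks_at_grating_parameters(self):
        """A pure grating at (f=8, 45 deg) maximizes the (8, 45 deg) filter's
        mean response magnitude across the whole bank."""
        n = 128
        bank = BankConfig(gabor_image_width=n)
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        theta = np.deg2rad(45.0)
        phase = 2 * np.pi * (8.0 / n) * (xx * np.cos(theta) + yy * np.sin(theta))
        img = np.cos(phase)
        mask = disk((n, n), (n // 2, n // 2), 40)
        feats = gabor_features(img, mask, bank)
        means = {k[: -len("__mean")]: v for k, v in feats.items() if
                 k.endswith("__mean") and not k.startswith("f0-")}
        assert max(means, key=means.get) == "f8-th45"

    def test_kernel_count_and_shape(self):
        k = gabor_kernel(8, 22.5)
        assert k.ndim == 2 and k.shape[0] == k.shape[1] and k.shape[0] % 2 == 1


class TestExtraction:
    @pytest.fixture(scope="class")
    def small_case(self):
        rng = np.random.default_rng(5)
        n = 128
        truth = disk((n, n), (64, 64), 12)
        b0 = np.full((n, n), 600.0) + rng.normal(0, 5, (n, n))
        b0[truth] = 650.0 + rng.normal(0, 20, truth.sum())
        adc = np.where(truth, 1.0e-3, 1.8e-3)
        b800 = b0 * np.exp(-800 * adc) + rng.normal(0, 3, (n, n))
        stack = ImageStack(b0=b0, b800=np.clip(b800, 1, None),
                           pixel_spacing_mm=1.328125)
        ring = peritumoral_ring(truth, 4.0, 1.328125)
        return stack, RoiSet(truth, ring)

    def test_full_bank_length_and_finiteness(self, small_case):
        stack, rois = small_case
        vec = extract_features(stack, rois)
        assert len(vec) == 2504
        assert np.isfinite(vec.to_numpy()).all()
        assert list(vec.index) == feature_names()

    def test_translation_invariance(self, small_case):
        """Shifting image and masks together by whole pixels leaves all
        non-shape features unchanged."""
        stack, rois = small_case
        vec = extract_features(stack, rois)
        shift = (-6, 9)
        roll = lambda a: np.roll(np.roll(a, shift[0], axis=0), shift[1], axis=1)
        stack2 = ImageStack(
            b0=roll(stack.b0), b800=roll(stack.b800),
            pixel_spacing_mm=stack.pixel_spacing_mm,
        )
        rois2 = RoiSet(roll(rois.intratumoral), roll(rois.peritumoral))
        vec2 = extract_features(stack2, rois2)
        texture = [n for n in vec.index if not n.startswith("shape__")]
        np.testing.assert_allclose(
            vec[texture].to_numpy(), vec2[texture].to_numpy(), atol=1e-9, rtol=1e-9
        )


class TestZScore:
    def test_hand_computed_column(self):
        train = FeatureTable(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        (z_train,), _ = zscore_fit_apply(train)
        np.testing.assert_allclose(
            z_train.data["f"], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_training_columns_standardized(self, rng):
        train = FeatureTable(pd.DataFrame(rng.normal(2, 3, (50, 4)),
                                          columns=list("abcd")))
        other = FeatureTable(pd.DataFrame(rng.normal(2, 3, (20, 4)),
                                          columns=list("abcd")))
        (z_train, z_other), params = zscore_fit_apply(train, other)
        np.testing.assert_allclose(z_train.data.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z_train.data.std(ddof=0), 1.0, atol=1e-9)
        # other table transformed with training parameters, not its own
        assert not np.allclose(z_other.data.mean(), 0.0, atol=1e-3)

    def test_constant_column_flagged(self):
        train = FeatureTable(
            pd.DataFrame({"f": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        )
        with pytest.warns(UserWarning):
            (z_train,), params = zscore_fit_apply(train)
        assert (z_train.data["c"] == 0).all()
        assert bool(params.loc["c", "degenerate"])

    def test_column_mismatch_rejected(self):
        a = FeatureTable(pd.DataFrame({"f": [1.0, 2.0]}))
        b = FeatureTable(pd.DataFrame({"g": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            zscore_fit_apply(a, b)
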