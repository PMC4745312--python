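"""Tests of shape, histogram and texture features against brute-force oracles."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cellcull import features as ft
from cellcull import synthetic

from .conftest import make_object
from .oracles import (eccentricity_from_moments, entropy_bruteforce,
                      glcm_energy_bruteforce, solidity_from_hull)


def _random_mask(seed, shape=(20, 20), p=0.4):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < p
    mask[8:12, 8:12] = True  # guarantee enough pixels
    return mask


class TestEccentricity:
    def test_disk_is_round(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 25)
        mask[rr, cc] = True
        assert ft.eccentricity(mask) == pytest.approx(0.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        mask = np.zeros((80, 120), bool)
        rr, cc = draw_ellipse(40, 60, 20, 40)
        mask[rr, cc] = True
        assert ft.eccentricity(mask) == pytest.approx(np.sqrt(3) / 2, abs=0.02)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_moment_eigenvalue_oracle(self, seed):
        mask = _random_mask(seed)
        assert ft.eccentricity(mask) == pytest.approx(
            eccentricity_from_moments(mask), abs=1e-6)

    def test_rotation_invariance_within_tolerance(self):
        mask = np.zeros((80, 120), bool)
        rr, cc = draw_ellipse(40, 60, 15, 35)
        mask[rr, cc] = True
        assert ft.eccentricity(np.rot90(mask)) == pytest.approx(
            ft.eccentricity(mask), abs=0.02)

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            ft.eccentricity(np.eye(2, dtype=bool))


class TestSolidity:
    def test_rectangle_is_solid(self):
        mask = np.zeros((20, 20), bool)
        mask[4:16, 6:14] = True
        assert ft.solidity(mask) == pytest.approx(1.0, abs=0.01)

    def test_cross_shape_below_09(self):
        mask = np.zeros((30, 30), bool)
        mask[12:18, 2:28] = True
        mask[2:28, 12:18] = True
        val = ft.solidity(mask)
        assert val < 0.9
        assert val == pytest.approx(solidity_from_hull(mask), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hull_oracle(self, seed):
        mask = _random_mask(seed, p=0.2)
        assert ft.solidity(mask) == pytest.approx(
            solidity_from_hull(mask), abs=1e-9)

    def test_carving_concavity_decreases_solidity(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = draw_disk((20, 20), 15)
        mask[rr, cc] = True
        carved = mask.copy()
        rr, cc = draw_disk((20, 35), 8)
        keep = (rr < 40) & (cc < 40)
        carved[rr[keep], cc[keep]] = False
        assert ft.solidity(carved) < ft.solidity(mask)


class TestHistogramFeatures:
    def test_constant_region(self):
        gray = np.full((8, 8), 50.0)
        mask = np.ones((8, 8), bool)
        assert ft.normalized_variance(gray, mask) == 0.0
        assert ft.entropy(gray, mask) == 0.0
        with pytest.raises(ValueError):
            ft.normalized_kurtosis(gray, mask)

    def test_two_point_symmetric_distribution(self):
        gray = np.zeros((2, 2))
        gray[0, :] = 2.0  # equal mix of {0, 2}: mu=1, var=1
        mask = np.ones((2, 2), bool)
        assert ft.normalized_variance(gray, mask) == pytest.approx(1.0)
        assert ft.normalized_kurtosis(gray, mask) == pytest.approx(1.0)

    def test_gaussian_kurtosis_is_three(self):
        rng = np.random.default_rng(0)
        gray = rng.normal(100, 10, size=(400, 250))
        mask = np.ones(gray.shape, bool)
        assert ft.normalized_kurtosis(gray, mask) == pytest.approx(3.0, abs=0.05)

    def test_zero_mean_rejected(self):
        gray = np.array([[-1.0, 1.0]])
        with pytest.raises(ValueError):
            ft.normalized_variance(gray, np.ones((1, 2), bool))

    def test_uniform_histogram_entropy_is_eight_bits(self):
        gray = np.arange(256.0).reshape(16, 16)
        assert ft.entropy(gray, np.ones((16, 16), bool)) == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_entropy_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.uniform(0, 255, size=(12, 12))
        mask = _random_mask(seed, (12, 12))
        assert ft.entropy(gray, mask) == pytest.approx(
            entropy_bruteforce(gray, mask), abs=1e-9)

    def test_masked_only(self):
        rng = np.random.default_rng(1)
        gray = rng.uniform(10, 240, size=(10, 10))
        mask = _random_mask(3, (10, 10))
        poisoned = gray.copy()
        poisoned[~mask] = 255.0
        for fn in (ft.entropy, ft.normalized_variance, ft.normalized_kurtosis):
            assert fn(poisoned, mask) == fn(gray, mask)


class TestGLCM:
    def test_constant_region_energy_one(self):
        gray = np.full((12, 12), 77.0)
        assert ft.glcm_energy(gray, np.ones((12, 12), bool)) == 1.0

    def test_stripes_below_constant(self):
        gray = np.zeros((16, 16))
        gray[::2, :] = 200.0
        mask = np.ones((16, 16), bool)
        assert ft.glcm_energy(gray, mask) < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.uniform(0, 255, size=(8, 8))
        mask = rng.random((8, 8)) < 0.8
        if not mask.any():
            mask[4, 4] = True
        try:
            ours = ft.glcm_energy(gray, mask)
        except ValueError:
            with pytest.raises(ValueError):
                glcm_energy_bruteforce(gray, mask)
            return
        assert ours == pytest.approx(
            glcm_energy_bruteforce(gray, mask), abs=1e-12)

    def test_no_valid_pairs_raises(self):
        gray = np.zeros((4, 4))  # too small for offset 5
        with pytest.raises(ValueError, match="pairs"):
            ft.glcm_energy(gray, np.ones((4, 4), bool))


class TestGabor:
    def test_constant_crop_zero_variance(self):
        gray = np.full((40, 40), 120.0)
        assert ft.gabor_variance(gray, np.ones((40, 40), bool)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_grating_response_maximal_at_matching_orientation(self):
        x = np.arange(64)
        grating = np.tile(100 + 50 * np.cos(2 * np.pi * 0.1 * x), (64, 1))
        mask = np.ones((64, 64), bool)
        from scipy.signal import fftconvolve
        variances = []
        for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
            k = ft.gabor_kernel(theta)
            variances.append(fftconvolve(grating, k, mode="same")[mask].var())
        assert np.argmax(variances) == 0

    def test_quarter_rotation_leaves_average_invariant(self):
        rng = np.random.default_rng(2)
        gray = rng.uniform(0, 255, size=(48, 48))
        mask = np.ones((48, 48), bool)
        a = ft.gabor_variance(gray, mask)
        b = ft.gabor_variance(np.rot90(gray), mask)
        assert a == pytest.approx(b, rel=1e-6)


class TestRegistry:
    def test_core_registry_is_seven_features(self, suitable_object):
        vec = ft.compute_features(suitable_object, ft.CORE_FEATURES)
        assert len(vec) == 7
        assert set(vec) == set(ft.CORE_FEATURES)
        assert all(np.isfinite(v) for v in vec.values())

    def test_full_registry_covers_all_categories(self, suitable_object):
        vec = ft.compute_features(suitable_object, ft.FULL_REGISTRY)
        assert set(ft.CORE_FEATURES) <= set(vec)
        assert len(vec) >= 40

    def test_determinism(self, suitable_object):
        a = ft.compute_features(suitable_object, ft.FULL_REGISTRY)
        b = ft.compute_features(suitable_object, ft.FULL_REGISTRY)
        assert a == b

    def test_translation_invariance_of_shape_features(self, suitable_object):
        mask = suitable_object.mask
        padded = np.pad(mask, ((7, 3), (2, 9)))
        assert ft.eccentricity(padded) == pytest.approx(
            ft.eccentricity(mask), abs=1e-12)
        assert ft.solidity(padded) == pytest.approx(
            ft.solidity(mask), abs=1e-12)

    def test_suitable_vs_folded_feature_directions(self, suitable_object,
                                                   folded_object):
        """Matched suitable/folded pair reproduces the expected qualitative
        ordering: folded cells are more eccentric, less solid, noisier and
        less homogeneous in texture."""
        s = ft.compute_features(suitable_object, ft.CORE_FEATURES)
        u = ft.compute_features(folded_object, ft.CORE_FEATURES)
        assert u["eccentricity"] > s["eccentricity"]
        assert u["solidity"] < s["solidity"]
        assert u["normalized_variance"] > s["normalized_variance"]
        assert u["normalized_kurtosis"] < s["normalized_kurtosis"]
        assert u["entropy"] > s["entropy"]
        assert u["glcm_energy"] < s["glcm_energy"]
        assert u["gabor_variance"] > s["gabor_variance"]

    def test_unknown_feature_name(self, suitable_object):
        with pytest.raises(ValueError, match="unknown feature"):
            ft.compute_features(suitable_object, ["sparkliness"])

    def test_feature_table_shape_and_labels(self, suitable_object,
                                            folded_object):
        table = ft.compute_feature_table([suitable_object, folded_object],
                                         "core")
        assert table.shape == (2, 8)  # 7 features + label
        assert list(table["label"]) == ["suitable", "unsuitable"]
        assert np.isfinite(table.drop(columns="label").to_numpy()).all()
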