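"""Feature bank: transforms, discretization, and oracle equivalence of every
texture class against independent brute-force implementations."""

import numpy as np
import pytest

from strokesep.features import (
    DiscretizationConfig,
    ExtractionConfig,
    apply_transform,
    discretize,
    extract_all,
    feature_registry,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    gldm_features,
    glszm_features,
    ngtdm_features,
)
from strokesep.image import ImageSlice, ROIMask

from .conftest import random_roi
from . import oracles


@pytest.fixture(scope="module")
def scene():
    rng = np.random.default_rng(1)
    image = ImageSlice(rng.normal(30.0, 8.0, (32, 32)))
    mask = np.zeros((32, 32), bool)
    mask[8:24, 8:24] = True
    return image, ROIMask(mask)


class TestTransforms:
    def test_original_is_identity(self, scene):
        image, mask = scene
        out = apply_transform(image, mask, "original")
        assert np.array_equal(out.values, image.values)

    def test_constant_image_has_zero_detail_subbands(self, scene):
        _, mask = scene
        const = ImageSlice(np.full((32, 32), 17.0))
        for band in ("wavelet_LH", "wavelet_HL", "wavelet_HH"):
            out = apply_transform(const, mask, band)
            assert np.allclose(out.values[mask.mask], 0.0)

    def test_square_matches_hand_arithmetic(self, scene):
        """Shift to >= 1, square, rescale linearly to the ROI intensity range."""
        image, mask = scene
        out = apply_transform(image, mask, "square")
        v = image.values
        roi = mask.mask
        vmin, vmax = v[roi].min(), v[roi].max()
        shifted = np.clip(v - vmin + 1.0, 1.0, None)
        t = shifted**2
        expected = vmin + (t - t[roi].min()) * (vmax - vmin) / (t[roi].max() - t[roi].min())
        for r, c in [(10, 10), (12, 20), (23, 9)]:
            assert out.values[r, c] == pytest.approx(expected[r, c], abs=1e-12)

    def test_transforms_preserve_intensity_ordering_in_roi(self, scene):
        image, mask = scene
        base_order = np.argsort(image.values[mask.mask])
        for kind in ("square", "squareroot", "logarithm", "exponential"):
            out = apply_transform(image, mask, kind)
            assert np.array_equal(np.argsort(out.values[mask.mask]), base_order)

    def test_unknown_kind_rejected(self, scene):
        image, mask = scene
        with pytest.raises(ValueError):
            apply_transform(image, mask, "sobel")


class TestDiscretize:
    def test_fixed_width_arithmetic(self):
        values = np.array([[0.0, 5.0, 10.0, 15.0]])
        mask = np.ones((1, 4), bool)
        levels, ng = discretize(values, mask, DiscretizationConfig(bin_width=5.0))
        assert levels.tolist() == [[1, 2, 3, 4]]
        assert ng == 4

    def test_constant_roi_collapses_to_single_level(self):
        values = np.full((3, 3), 7.0)
        levels, ng = discretize(values, np.ones((3, 3), bool))
        assert ng == 1
        assert (levels == 1).all()

    def test_fixed_count_matches_histogram_binning(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(12, 12)) * 10
        mask = rng.random((12, 12)) < 0.8
        cfg = DiscretizationConfig(mode="fixed_bin_count", bin_count=8)
        levels, ng = discretize(values, mask, cfg)
        assert ng <= 8
        roi = values[mask]
        edges = np.linspace(roi.min(), roi.max(), 9)
        expected, _ = np.histogram(roi, bins=edges)
        observed = np.bincount(levels[mask], minlength=9)[1:]
        assert np.array_equal(observed, expected)

    def test_levels_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        values = rng.normal(30, 10, (10, 10))
        mask = np.ones((10, 10), bool)
        a, _ = discretize(values, mask)
        b, _ = discretize(values + 123.0, mask)
        assert np.array_equal(a, b)


class TestFirstOrder:
    def test_closed_form_on_one_to_ten(self):
        values = np.arange(1.0, 11.0).reshape(2, 5)
        f = first_order_features(ImageSlice(values), ROIMask(np.ones((2, 5), bool)))
        assert f["Mean"] == pytest.approx(5.5)
        assert f["Median"] == pytest.approx(5.5)
        assert f["Range"] == pytest.approx(9.0)
        assert f["10Percentile"] == pytest.approx(1.9)

    def test_constant_roi_degenerate_values(self):
        values = np.full((3, 4), 3.0)
        f = first_order_features(ImageSlice(values), ROIMask(np.ones((3, 4), bool)))
        assert f["Energy"] == pytest.approx(12 * 9.0)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            levels, mask = random_roi(rng)
            values = rng.normal(20, 10, levels.shape)
            image = ImageSlice(values)
            got = first_order_features(image, ROIMask(mask))
            lv, _ = discretize(values, mask)
            want = oracles.first_order_oracle(values, mask, lv)
            for name, w in want.items():
                if name == "TotalEnergy":
                    w *= image.spacing[0] * image.spacing[1]
                assert got[name] == pytest.approx(w, abs=1e-9), name

    def test_mean_equivariant_to_shift(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(6, 6))
        mask = np.ones((6, 6), bool)
        a = first_order_features(ImageSlice(values), ROIMask(mask))
        b = first_order_features(ImageSlice(values + 100.0), ROIMask(mask))
        assert b["Mean"] == pytest.approx(a["Mean"] + 100.0)
        assert b["Entropy"] == pytest.approx(a["Entropy"])  # bins shift with min


class TestGLCM:
    def test_two_by_two_hand_enumeration(self):
        levels = np.array([[1, 1], [2, 2]])
        mask = np.ones((2, 2), bool)
        p = glcm_matrix(levels, mask, 1, 0)
        assert np.allclose(p, [[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(levels, mask, (1,), (0,))
        assert f["Contrast"] == 0.0
        assert f["MaximumProbability"] == 0.5

    def test_constant_roi_degenerate(self):
        levels = np.ones((3, 3), dtype=np.int64)
        mask = np.ones((3, 3), bool)
        f = glcm_features(levels, mask)
        assert f["JointEnergy"] == 1.0
        assert f["JointEntropy"] == 0.0
        assert f["Correlation"] == 1.0

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            levels, mask = random_roi(rng)
            for ang in (0, 45, 90, 135):
                p = glcm_matrix(levels, mask, 1, ang)
                if p.sum() > 0:
                    assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            levels, mask = random_roi(rng)
            got = glcm_features(levels, mask)
            want = oracles.glcm_features_oracle(levels, mask)
            for name, w in want.items():
                assert got[name] == pytest.approx(w, abs=1e-9), name


class TestGLRLM:
    def test_single_row_hand_runs(self):
        levels = np.array([[1, 1, 1, 2]])
        mask = np.ones((1, 4), bool)
        f = glrlm_features(levels, mask, angles=(0,))
        assert f["RunPercentage"] == pytest.approx(2 / 4)

    def test_constant_single_row_long_run(self):
        n = 7
        levels = np.ones((1, n), dtype=np.int64)
        mask = np.ones((1, n), bool)
        f = glrlm_features(levels, mask, angles=(0,))
        assert f["LongRunEmphasis"] == pytest.approx(n**2)
        assert f["RunEntropy"] == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            levels, mask = random_roi(rng)
            got = glrlm_features(levels, mask)
            want = oracles.glrlm_features_oracle(levels, mask)
            for name, w in want.items():
                assert got[name] == pytest.approx(w, abs=1e-9), name


class TestAuxiliaryClasses:
    def test_constant_roi_single_zone(self):
        levels = np.ones((3, 3), dtype=np.int64)
        mask = np.ones((3, 3), bool)
        f = glszm_features(levels, mask)
        assert f["LargeAreaEmphasis"] == pytest.approx(81.0)  # one zone of size 9
        assert f["ZonePercentage"] == pytest.approx(1 / 9)

    def test_checkerboard_zones_under_eight_connectivity(self):
        """Diagonally touching same-level cells merge into one zone."""
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4), bool)
        zones = oracles.zones_oracle(levels, mask)
        assert len(zones) == 2  # each color forms a single 8-connected zone
        f = glszm_features(levels, mask)
        assert f["ZonePercentage"] == pytest.approx(2 / 16)

    @pytest.mark.parametrize(
        "impl,oracle",
        [
            (glszm_features, oracles.glszm_features_oracle),
            (gldm_features, oracles.gldm_features_oracle),
            (ngtdm_features, oracles.ngtdm_features_oracle),
        ],
        ids=["glszm", "gldm", "ngtdm"],
    )
    def test_matches_bruteforce_oracle(self, impl, oracle):
        rng = np.random.default_rng(9)
        for _ in range(50):
            levels, mask = random_roi(rng)
            got = impl(levels, mask)
            want = oracle(levels, mask)
            for name, w in want.items():
                assert got[name] == pytest.approx(w, abs=1e-9), name


@pytest.fixture(scope="module")
def region():
    rng = np.random.default_rng(4)
    image = ImageSlice(rng.normal(30, 6, (64, 64)))
    mask = np.zeros((64, 64), bool)
    mask[20:44, 22:46] = True
    return image, ROIMask(mask)


class TestExtractAll:
    def test_default_registry_has_930_features(self):
        assert len(feature_registry()) == 930

    def test_vector_matches_registry_and_is_deterministic(self, region):
        image, mask = region
        a = extract_all(image, mask)
        b = extract_all(image, mask)
        assert list(a) == feature_registry()
        assert a == b
        assert all(np.isfinite(v) for v in a.values())

    def test_reduced_config_counts(self, region):
        image, mask = region
        cfg = ExtractionConfig(transforms=("original",), classes=("firstorder",))
        vec = extract_all(image, mask, cfg)
        assert len(vec) == 18

    def test_pixels_far_outside_mask_do_not_matter(self, region):
        image, mask = region
        altered = image.values.copy()
        altered[0, 0] += 500.0  # outside the padded bounding box
        a = extract_all(image, mask)
        b = extract_all(ImageSlice(altered, image.spacing), mask)
        assert a == b
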