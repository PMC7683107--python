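"""Synthetic head phantom and cohort generator contracts."""

import numpy as np
import pytest

from strokesep.image import ImageSlice, ROIMask
from strokesep.phantom import (
    LesionSpec,
    PhantomSpec,
    generate_cohort,
    generate_head_slice,
    inject_lesion,
    sample_lesion_roi,
)

SHAPE = (256, 256)


class TestHeadSlice:
    def test_noise_free_slice_is_exactly_mirror_symmetric(self):
        spec = PhantomSpec(image_shape=SHAPE, noise_sd=0.0, asymmetry_jitter=0.0)
        image, brain = generate_head_slice(spec, seed=4)
        assert np.array_equal(image.values, image.values[:, ::-1])
        assert np.array_equal(brain.mask, brain.mask[:, ::-1])

    def test_same_seed_gives_bit_identical_slices(self):
        spec = PhantomSpec(image_shape=SHAPE)
        a, _ = generate_head_slice(spec, seed=9)
        b, _ = generate_head_slice(spec, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_noise_amplitude_matches_configured_sd(self):
        """Sample SD of (noisy - noise-free) inside the brain ~ noise_sd."""
        clean_spec = PhantomSpec(image_shape=SHAPE, noise_sd=0.0, asymmetry_jitter=0.0)
        noisy_spec = PhantomSpec(
            image_shape=SHAPE, noise_sd=5.0, noise_corr_len=2.0, asymmetry_jitter=0.0
        )
        clean, brain = generate_head_slice(clean_spec, seed=3)
        noisy, _ = generate_head_slice(noisy_spec, seed=3)
        sd = (noisy.values - clean.values)[brain.mask].std()
        assert abs(sd - 5.0) / 5.0 < 0.15

    def test_tissue_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(mean_white=50.0, mean_gray=40.0)

    def test_rejects_non_positive_shape(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_shape=(0, 256))


@pytest.fixture(scope="module")
def brain():
    spec = PhantomSpec(image_shape=SHAPE, noise_sd=0.0, asymmetry_jitter=0.0)
    _, brain = generate_head_slice(spec, seed=4)
    return brain


class TestLesionRoi:
    def test_zero_irregularity_gives_exact_disk(self, brain):
        spec = LesionSpec(center=(128.0, 80.0), mean_radius=10.0, boundary_irregularity=0.0)
        roi = sample_lesion_roi(brain, spec)
        rr = np.arange(SHAPE[0])[:, None] - 128.0
        cc = np.arange(SHAPE[1])[None, :] - 80.0
        disk = np.hypot(rr, cc) <= 10.0
        assert np.array_equal(roi.mask, disk)

    def test_different_seeds_give_different_blobs(self, brain):
        a = sample_lesion_roi(brain, LesionSpec(center=(128.0, 80.0), seed=1))
        b = sample_lesion_roi(brain, LesionSpec(center=(128.0, 80.0), seed=2))
        assert not np.array_equal(a.mask, b.mask)

    def test_blob_areas_within_factor_two_of_disk(self, brain):
        """Monte-Carlo check of the area contract at irregularity 0.3."""
        target = np.pi * 15.0**2
        for seed in range(100):
            spec = LesionSpec(
                center=(128.0, 75.0), mean_radius=15.0, boundary_irregularity=0.3, seed=seed
            )
            area = sample_lesion_roi(brain, spec).area
            assert target / 2 < area < target * 2

    def test_rejects_blob_crossing_midline(self, brain):
        with pytest.raises(ValueError, match="midline"):
            sample_lesion_roi(brain, LesionSpec(center=(128.0, 127.0), mean_radius=10.0))

    def test_rejects_blob_outside_brain(self, brain):
        with pytest.raises(ValueError, match="brain"):
            sample_lesion_roi(brain, LesionSpec(center=(10.0, 10.0), mean_radius=8.0))


@pytest.fixture(scope="module")
def scene():
    spec = PhantomSpec(image_shape=SHAPE)
    image, brain = generate_head_slice(spec, seed=12)
    lspec = LesionSpec(center=(140.0, 80.0), mean_radius=12.0, seed=5)
    roi = sample_lesion_roi(brain, lspec)
    return image, roi


class TestInjectLesion:
    def test_zero_effect_is_identity(self, scene):
        image, roi = scene
        null = LesionSpec(delta_hu=0.0, smooth_sigma=0.0)
        out = inject_lesion(image, roi, null)
        assert np.array_equal(out.values, image.values)

    def test_mean_shift_matches_delta(self, scene):
        image, roi = scene
        spec = LesionSpec(delta_hu=-6.0, smooth_sigma=0.0)
        out = inject_lesion(image, roi, spec)
        shift = (out.values - image.values)[roi.mask].mean()
        assert abs(shift - (-6.0)) < 1.0

    def test_smoothing_reduces_variance(self, scene):
        image, roi = scene
        spec = LesionSpec(delta_hu=0.0, smooth_sigma=2.0)
        out = inject_lesion(image, roi, spec)
        assert out.values[roi.mask].var() < image.values[roi.mask].var()

    def test_pixels_outside_roi_untouched(self, scene):
        image, roi = scene
        out = inject_lesion(image, roi, LesionSpec())
        assert np.array_equal(out.values[~roi.mask], image.values[~roi.mask])

    def test_mean_shift_unbiased_over_noise_seeds(self):
        """E[mean(roi, lesioned) - mean(roi, clean)] = delta_hu within 2 SE."""
        lspec = LesionSpec(center=(150.0, 85.0), mean_radius=12.0,
                           boundary_irregularity=0.0, delta_hu=-6.0, smooth_sigma=1.5)
        shifts = []
        for seed in range(50):
            spec = PhantomSpec(image_shape=SHAPE)
            image, brain = generate_head_slice(spec, seed=seed)
            roi = sample_lesion_roi(brain, lspec)
            out = inject_lesion(image, roi, lspec)
            shifts.append((out.values - image.values)[roi.mask].mean())
        shifts = np.asarray(shifts)
        se = shifts.std(ddof=1) / np.sqrt(len(shifts))
        assert abs(shifts.mean() - (-6.0)) < max(2 * se, 0.05)

    def test_rejects_mismatched_shapes(self, scene):
        image, _ = scene
        bad = ROIMask(np.ones((10, 10), bool))
        with pytest.raises(ValueError):
            inject_lesion(image, bad, LesionSpec())


@pytest.fixture(scope="module")
def cohort():
    spec = PhantomSpec(image_shape=SHAPE)
    return generate_cohort(3, 2, spec=spec, seed=42)


class TestCohort:
    def test_slice_counts_per_group(self, cohort):
        lesions = [s for s in cohort if s.group == "lesion"]
        normals = [s for s in cohort if s.group == "normal"]
        assert [len(s.slices) for s in lesions] == [1, 1, 1]
        assert [len(s.slices) for s in normals] == [3, 3]

    def test_total_region_bookkeeping(self, cohort):
        records = sum(len(s.slices) for s in cohort)
        assert records == 3 * 1 + 2 * 3

    def test_deterministic_per_seed(self):
        spec = PhantomSpec(image_shape=SHAPE)
        a = generate_cohort(2, 1, spec=spec, seed=7)
        b = generate_cohort(2, 1, spec=spec, seed=7)
        for sa, sb in zip(a, b):
            for ra, rb in zip(sa.slices, sb.slices):
                assert np.array_equal(ra.image.values, rb.image.values)
                assert np.array_equal(ra.roi.mask, rb.roi.mask)

    def test_every_roi_inside_brain_and_one_hemisphere(self, cohort):
        for subject in cohort:
            for rec in subject.slices:
                assert rec.roi.area > 0
                assert not (rec.roi.mask & ~rec.brain.mask).any()

    def test_rejects_empty_groups(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1, seed=0)
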