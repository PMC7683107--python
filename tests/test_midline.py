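"""Midline estimation and ROI mirroring geometry."""

import numpy as np
import pytest

from strokesep.image import ImageSlice, ROIMask
from strokesep.midline import (
    MidlineParams,
    estimate_midline,
    make_candidate_pairs,
    mirror_roi,
    reflection_matrix,
)
from strokesep.phantom import (
    LesionSpec,
    PhantomSpec,
    apply_pose,
    generate_cohort,
    generate_head_slice,
    pose_midline,
    sample_lesion_roi,
)


def _reflect_point(point, midline, shape):
    m = reflection_matrix(midline, shape)
    return (m @ np.array([point[0], point[1], 1.0]))[:2]


class TestEstimateMidline:
    def test_symmetric_phantom_recovers_centered_vertical_axis(self, small_phantom):
        image, brain = small_phantom
        ml = estimate_midline(image, brain)
        assert ml.offset == 0.0 and ml.angle == 0.0

    @pytest.mark.parametrize("angle,shift", [(4.0, (0.0, 0.0)), (0.0, (0.0, 10.0))])
    def test_recovers_known_pose(self, noisy_phantom, angle, shift):
        image, brain = noisy_phantom
        vals, bm = apply_pose([image.values, brain.mask], angle, shift, orders=[1, 0])
        ml = estimate_midline(ImageSlice(vals), ROIMask(bm))
        true_offset, true_angle = pose_midline(angle, shift)
        assert abs(ml.angle - true_angle) <= 1.0
        assert abs(ml.offset - true_offset) <= 1.0

    def test_unbiased_on_noisy_symmetric_phantoms(self):
        offsets = []
        for seed in range(50):
            spec = PhantomSpec(image_shape=(256, 256))
            image, brain = generate_head_slice(spec, seed=200 + seed)
            offsets.append(abs(estimate_midline(image, brain).offset))
        assert np.mean(offsets) <= 1.0

    def test_rejects_degenerate_mask(self, small_phantom):
        image, _ = small_phantom
        tiny = np.zeros(image.shape, bool)
        tiny[10:13, 10:13] = True
        with pytest.raises(ValueError):
            estimate_midline(image, ROIMask(tiny))


@pytest.fixture(scope="module")
def masks():
    rng = np.random.default_rng(0)
    out = []
    for _ in range(50):
        mask = np.zeros((256, 256), bool)
        r = int(rng.integers(60, 200))
        c = int(rng.integers(60, 110))
        rad = int(rng.integers(5, 20))
        rr = np.arange(256)[:, None] - r
        cc = np.arange(256)[None, :] - c
        mask[np.hypot(rr, cc) <= rad] = True
        midline = MidlineParams(
            offset=float(rng.uniform(-10, 10)), angle=float(rng.uniform(-8, 8))
        )
        out.append((ROIMask(mask), midline))
    return out


class TestMirrorRoi:
    def test_symmetric_mask_is_fixed_point(self):
        mask = np.zeros((128, 128), bool)
        mask[40:60, 50:78] = True  # symmetric about the central column axis
        out = mirror_roi(ROIMask(mask), MidlineParams())
        assert np.array_equal(out.mask, mask)

    def test_area_preserved_within_two_percent(self, masks):
        for mask, midline in masks:
            out = mirror_roi(mask, midline)
            assert abs(out.area - mask.area) <= 0.02 * mask.area

    def test_involution_dice(self, masks):
        for mask, midline in masks:
            twice = mirror_roi(mirror_roi(mask, midline), midline)
            inter = (twice.mask & mask.mask).sum()
            dice = 2 * inter / (twice.area + mask.area)
            assert dice >= 0.95

    def test_centroid_reflects_across_line(self, masks):
        for mask, midline in masks:
            out = mirror_roi(mask, midline)
            want = _reflect_point(mask.centroid(), midline, mask.shape)
            got = np.array(out.centroid())
            assert np.all(np.abs(got - want) <= 1.0)

    def test_fails_when_reflection_leaves_image(self):
        mask = np.zeros((128, 128), bool)
        mask[60:70, 2:10] = True
        with pytest.raises(ValueError):
            mirror_roi(ROIMask(mask), MidlineParams(offset=-62.0))


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(2, 1, spec=PhantomSpec(image_shape=(256, 256)), seed=5)


class TestCandidatePairs:
    def test_pair_counts_and_labels(self, cohort):
        lesion_subject = next(s for s in cohort if s.group == "lesion")
        normal_subject = next(s for s in cohort if s.group == "normal")
        lp = make_candidate_pairs(lesion_subject)
        assert len(lp) == 1
        assert [r.label for r in lp[0]] == ["lesion", "mirror"]
        np_pairs = make_candidate_pairs(normal_subject)
        assert len(np_pairs) == 3
        for a, b in np_pairs:
            assert (a.label, b.label) == ("normal", "normal_mirror")

    def test_lesion_and_mirror_are_disjoint(self, cohort):
        for subject in cohort:
            for a, b in make_candidate_pairs(subject):
                assert not (a.mask.mask & b.mask.mask).any()

    def test_mirror_lands_on_contralateral_side(self, cohort):
        """The mirrored ROI must sit in the opposite hemisphere, at roughly
        the reflected position of the original."""
        subject = next(s for s in cohort if s.group == "lesion")
        rec = subject.slices[0]
        (orig, mirr), = make_candidate_pairs(subject)
        true_off, true_ang = subject.true_midline
        c = np.array(rec.image.center)
        oc = np.array(orig.mask.centroid())
        mc = np.array(mirr.mask.centroid())
        want = _reflect_point(oc, MidlineParams(offset=true_off, angle=true_ang), rec.image.shape)
        assert np.linalg.norm(mc - want) <= 4.0
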