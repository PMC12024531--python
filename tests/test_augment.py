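"""Rotational augmentation geometry and normalization statistics."""
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from euslite import augment as ag
from euslite import phantom
from euslite.errors import ConfigError, MarginError


def _frame(pixels, center):
    return ag.ProbeFrame(pixels=pixels, probe_center=center, source_id="s",
                         patient_id="p", label="GIST")


class TestRotationAngles:
    def test_default_step_yields_fifteen_extra_variants(self):
        assert len(ag.rotation_angles(22.5)) == 15

    def test_quarter_step(self):
        assert ag.rotation_angles(90) == [90, 180, 270]

    def test_full_turn_is_identity_only(self):
        assert ag.rotation_angles(360) == []

    def test_non_divisor_rejected(self):
        with pytest.raises(ConfigError):
            ag.rotation_angles(50)

    @given(st.sampled_from([10, 15, 22.5, 30, 45, 60, 90, 120, 180, 360]))
    @settings(max_examples=10, deadline=None)
    def test_cardinality_is_turns_minus_one(self, step):
        assert len(ag.rotation_angles(step)) == round(360 / step) - 1


class TestCropCentered:
    def test_exact_subarray(self, rng):
        img = rng.random((10, 10))
        crop = ag.crop_centered(_frame(img, (5.0, 5.0)), 4)
        assert np.array_equal(crop, img[3:7, 3:7])

    def test_clinical_frame_fits(self):
        crop = ag.crop_centered(_frame(np.zeros((500, 400)), (250.0, 200.0)), 360)
        assert crop.shape == (360, 360)

    def test_margin_error_names_edge(self):
        with pytest.raises(MarginError, match="top"):
            ag.crop_centered(_frame(np.zeros((500, 400)), (30.0, 200.0)), 360)


class TestAugmentImage:
    def test_sixteen_crops_at_default_step(self, rng):
        img = rng.random((600, 600))
        crops = ag.augment_image(_frame(img, (300.0, 300.0)), ag.AugmentConfig())
        assert len(crops) == 16
        assert all(c.shape == (360, 360) for c in crops)

    def test_identity_member_is_bitwise_crop(self, rng):
        img = rng.random((600, 600))
        frame = _frame(img, (300.0, 300.0))
        crops = ag.augment_image(frame, ag.AugmentConfig(angle_step_deg=90))
        assert np.array_equal(crops[0], ag.crop_centered(frame, 360))

    def test_quarter_turn_equals_exact_array_rotation(self, rng):
        img = rng.random((201, 201))
        frame = _frame(img, (100.0, 100.0))  # pixel-aligned symmetry point
        cfg = ag.AugmentConfig(angle_step_deg=90, crop_side=81,
                               interpolation="nearest")
        crops = ag.augment_image(frame, cfg)
        assert np.allclose(crops[1], np.rot90(crops[0], k=-1), atol=1e-6)

    def test_corner_validation_rejects_tight_clinical_geometry(self):
        # a centered 360-px box on a 500x400 frame leaves only a 200-px
        # column margin; the rotated corner radius (~254.6 px) exceeds it
        frame = _frame(np.zeros((500, 400)), (250.0, 200.0))
        with pytest.raises(MarginError, match="22.5"):
            ag.augment_image(frame, ag.AugmentConfig())

    def test_reflect_policy_warns_instead(self):
        frame = _frame(np.zeros((500, 400)), (250.0, 200.0))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            crops = ag.augment_image(
                frame, ag.AugmentConfig(margin_policy="reflect_pad_warn")
            )
        assert len(crops) == 16
        assert caught  # at least one reflection warning

    def test_crops_stay_in_unit_range(self, rng):
        img = rng.random((600, 600))
        crops = ag.augment_image(_frame(img, (300.0, 300.0)),
                                 ag.AugmentConfig(angle_step_deg=45))
        for c in crops:
            assert c.min() >= 0.0 and c.max() <= 1.0

    def test_mask_centroid_relocalizes_after_inverse_rotation(self):
        """Rotating a lesion mask and rotating back recovers the lesion
        centroid to within a pixel."""
        rec = phantom.render_frame(
            phantom.PhantomSpec(image_height=360, image_width=360, px_per_mm=3.5,
                                seed=5)
        )
        mask_frame = ag.ProbeFrame(rec.lesion_mask.astype(float),
                                   rec.frame.probe_center)
        cfg = ag.AugmentConfig(angle_step_deg=22.5, crop_side=200,
                               interpolation="nearest")
        crops = ag.augment_image(mask_frame, cfg)
        ref = crops[0]
        ref_centroid = np.array(np.nonzero(ref > 0.5)).mean(axis=1)
        for angle, crop in zip(ag.rotation_angles(22.5), crops[1:]):
            back_frame = ag.ProbeFrame(crop, (99.5, 99.5))
            # rotating by -angle undoes the rotation about the crop center
            undone = ag._rotated_crop(back_frame, 200, -angle, order=0,
                                      mode="constant")
            centroid = np.array(np.nonzero(undone > 0.5)).mean(axis=1)
            assert np.abs(centroid - ref_centroid).max() < 1.0


class TestNormalization:
    def test_constant_image(self):
        s = ag.compute_normalization([np.full((4, 4), 0.5)])
        assert s.mean == 0.5 and s.std == 0.0

    def test_two_single_pixels_population_std(self):
        s = ag.compute_normalization([np.array([[0.0]]), np.array([[1.0]])])
        assert s.mean == 0.5 and s.std == 0.5

    def test_empty_collection_rejected(self):
        with pytest.raises(ConfigError):
            ag.compute_normalization([])

    def test_matches_flatten_then_moment_oracle(self, rng):
        imgs = [rng.random((17, 13)) for _ in range(40)]
        s = ag.compute_normalization(imgs)
        flat = np.concatenate([i.ravel() for i in imgs])
        assert abs(s.mean - flat.mean()) < 1e-12
        assert abs(s.std - flat.std()) < 1e-12

    def test_apply_then_invert_roundtrip(self, rng):
        s = ag.NormalizationStats(0.4093, 0.2018)
        x = rng.random((5, 5))
        assert np.allclose(s.invert(s.apply(x)), x, atol=1e-9)
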