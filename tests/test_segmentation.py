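"""Segmentation stages: frame differencing, green filter, HSV bands, cleanup."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.color import hsv2rgb
from skimage.measure import label
from skimage.transform import SimilarityTransform, warp

from phenoshoot import segmentation as seg
from phenoshoot import synthetic_plants as synth
from phenoshoot.errors import InvalidArgumentError, RegistrationError


def hsv_pixel_image(h, s, v, shape=(8, 8)):
    img = hsv2rgb(np.broadcast_to([h, s, v], shape + (3,)).astype(float))
    return img


class TestFrameDifference:
    def test_identical_frames_give_empty_mask(self):
        img = np.random.default_rng(0).random((16, 16, 3))
        assert not seg.frame_difference(img, img, 15 / 255).any()

    def test_saturating_threshold_empties_mask(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((2, 16, 16, 3))
        assert not seg.frame_difference(a, b, 1.0).any()

    def test_dimension_mismatch_rejected(self):
        a = np.zeros((8, 8, 3))
        b = np.zeros((9, 8, 3))
        with pytest.raises(InvalidArgumentError):
            seg.frame_difference(a, b, 0.1)

    def test_plant_pixels_are_foreground(self, plant_spec):
        frame = synth.render_frame(plant_spec, 15)
        bg = synth.render_background(plant_spec)
        rough = seg.frame_difference(frame.rgb, bg, 15 / 255)
        assert (rough & frame.mask).sum() == frame.mask.sum()


class TestGreenSuperimpose:
    def test_empty_mask_zeroes_everything(self):
        img = np.random.default_rng(2).random((10, 10, 3))
        out = seg.green_superimpose(img, np.zeros((10, 10), bool))
        assert not out.any()

    def test_green_pixels_retained(self):
        img = hsv_pixel_image(0.33, 0.6, 0.6)
        out = seg.green_superimpose(img, np.ones((8, 8), bool))
        assert np.allclose(out, img)

    def test_soil_colored_pixels_removed(self):
        soil = hsv_pixel_image(0.08, 0.6, 0.45)  # brown: hue outside green band
        out = seg.green_superimpose(soil, np.ones((8, 8), bool))
        assert not out.any()


class TestHsvBinarize:
    @pytest.mark.parametrize(
        "hsv,expected",
        [
            ((0.33, 0.50, 0.50), True),   # mid-green inside every band
            ((0.33, 1.00, 0.50), False),  # saturation above band
            ((0.60, 0.50, 0.50), False),  # hue above band
        ],
    )
    def test_band_membership(self, hsv, expected):
        mask = seg.hsv_binarize(hsv_pixel_image(*hsv))
        assert mask.all() == expected and mask.any() == expected

    def test_black_never_foreground(self):
        assert not seg.hsv_binarize(np.zeros((8, 8, 3))).any()

    def test_idempotent_on_masked_output(self, plant_spec):
        frame = synth.render_frame(plant_spec, 15)
        mask = seg.hsv_binarize(frame.rgb)
        masked = frame.rgb * mask[..., None]
        assert np.array_equal(seg.hsv_binarize(masked), mask)

    @settings(max_examples=25, deadline=None)
    @given(
        widen=st.tuples(*[st.floats(0, 0.2) for _ in range(6)]),
        seed=st.integers(0, 2**16),
    )
    def test_widening_ranges_never_shrinks_mask(self, widen, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12, 3))
        base = seg.DEFAULT_HSV
        wide = seg.HsvRanges(
            hue=(max(0, base.hue[0] - widen[0]), min(1, base.hue[1] + widen[1])),
            saturation=(max(0, base.saturation[0] - widen[2]),
                        min(1, base.saturation[1] + widen[3])),
            value=(max(0, base.value[0] - widen[4]),
                   min(1, base.value[1] + widen[5])),
        )
        narrow_mask = seg.hsv_binarize(img, base)
        wide_mask = seg.hsv_binarize(img, wide)
        assert (narrow_mask & ~wide_mask).sum() == 0


class TestMorphologicalClean:
    def test_specks_removed_plant_kept(self, plant_spec):
        frame = synth.render_frame(plant_spec, 15)
        noisy = frame.mask.copy()
        rng = np.random.default_rng(3)
        specks = []
        while len(specks) < 10:
            r, c = rng.integers(0, noisy.shape[0]), rng.integers(0, noisy.shape[1])
            if not noisy[max(r - 3, 0):r + 4, max(c - 3, 0):c + 4].any():
                noisy[r, c] = True
                specks.append((r, c))
        clean = seg.morphological_clean(noisy)
        assert label(clean, connectivity=2).max() == 1
        assert not any(clean[r, c] for r, c in specks)
        assert (clean & frame.mask).sum() / frame.mask.sum() > 0.99

    def test_small_hole_filled(self):
        blob = np.zeros((40, 40), bool)
        blob[5:35, 5:35] = True
        blob[20, 20] = False
        clean = seg.morphological_clean(blob)
        assert clean[20, 20]

    def test_empty_mask_passthrough(self):
        out = seg.morphological_clean(np.zeros((10, 10), bool))
        assert not out.any()


class TestSegmentPipeline:
    def test_synthetic_frame_high_iou(self, plant_spec):
        frame = synth.render_frame(plant_spec, 20)
        bg = synth.render_background(plant_spec)
        mask = seg.segment(frame.rgb, bg)
        assert seg.mask_iou(mask, frame.mask) >= 0.98

    def test_background_only_frame_empty(self, plant_spec):
        bg = synth.render_background(plant_spec)
        assert not seg.segment(bg, bg).any()

    def test_illumination_gain_on_background_still_clean(self, plant_spec):
        frame = synth.render_frame(plant_spec, 20)
        bg = synth.render_background(plant_spec)
        bright = frame.rgb.astype(float) / 255.0
        gain = np.where(frame.mask[..., None], 1.0, 1.2)
        bright = np.clip(bright * gain, 0, 1)
        mask = seg.segment(bright, bg)
        assert seg.mask_iou(mask, frame.mask) >= 0.98

    def test_output_subset_of_hsv_mask(self, plant_spec):
        frame = synth.render_frame(plant_spec, 20)
        bg = synth.render_background(plant_spec)
        out = seg.segment(frame.rgb, bg)
        hsv_mask = seg.hsv_binarize(frame.rgb)
        assert not (out & ~hsv_mask).any()


def _textured_scene(seed=0, shape=(200, 220)):
    """Feature-rich scene (random blobs) for registration tests."""
    rng = np.random.default_rng(seed)
    img = np.full(shape + (3,), 0.9)
    for _ in range(40):
        r, c = rng.integers(20, shape[0] - 20), rng.integers(20, shape[1] - 20)
        h = rng.integers(3, 9)
        img[r:r + h, c:c + h] = rng.random(3)
    return img


class TestRegistration:
    def test_identity_for_identical_frames(self):
        scene = _textured_scene()
        model = seg.estimate_registration(scene, scene)
        assert model.scale == pytest.approx(1.0, abs=1e-3)
        assert model.rotation == pytest.approx(0.0, abs=1e-3)

    def test_recovers_known_scale(self):
        scene = _textured_scene(1)
        tf = SimilarityTransform(scale=1.2)
        scaled = warp(scene, tf.inverse)  # zoomed frame
        model = seg.estimate_registration(scaled, scene)
        assert model.scale == pytest.approx(1 / 1.2, rel=0.01)

    def test_featureless_frames_fail(self):
        flat = np.full((60, 60, 3), 0.5)
        with pytest.raises(RegistrationError):
            seg.estimate_registration(flat, flat)
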