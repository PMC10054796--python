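import numpy as np
import pytest

from fundcam.cropping import (BoundingBox, attention_crop_dataset, classic_augment,
                              crop_and_resize, min_bounding_rect, scale_to_byte,
                              threshold_mask)


def brute_force_box(mask):
    """Independent oracle: scan min/max occupied row and column indices."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return None
    return BoundingBox(x=int(xs.min()), y=int(ys.min()),
                       w=int(xs.max() - xs.min() + 1),
                       h=int(ys.max() - ys.min() + 1))


class TestScaleToByte:
    def test_linear_rescale_hand_case(self):
        out = scale_to_byte(np.array([[0.0, 1.0], [2.0, 4.0]]))
        np.testing.assert_allclose(out, [[0.0, 63.75], [127.5, 255.0]])

    def test_constant_map_goes_to_zero(self):
        np.testing.assert_array_equal(scale_to_byte(np.full((3, 3), 7.0)), 0.0)

    def test_full_range_map_unchanged(self):
        m = np.array([[0.0, 100.0], [200.0, 255.0]])
        np.testing.assert_allclose(scale_to_byte(m), m)

    def test_output_range_invariant(self, rng):
        out = scale_to_byte(rng.normal(size=(10, 10)))
        assert out.min() == 0.0 and out.max() == 255.0


class TestThresholdMask:
    def test_hand_compare(self):
        m = threshold_mask(np.array([[10.0, 200.0], [30.0, 250.0]]), 128)
        np.testing.assert_array_equal(m, [[0, 1], [0, 1]])

    def test_theta_255_all_zero_strict(self):
        assert threshold_mask(np.full((4, 4), 255.0), 255).sum() == 0

    def test_theta_0_positive_map_all_one(self):
        assert threshold_mask(np.full((4, 4), 1.0), 0).all()

    def test_theta_out_of_range_raises(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), 300)

    def test_monotone_in_theta(self, rng):
        """Raising theta never grows the mask or the box area."""
        bytemap = scale_to_byte(rng.random((24, 24)))
        prev_mask, prev_area = None, None
        for theta in [0, 64, 128, 192, 254]:
            mask = threshold_mask(bytemap, theta)
            box = min_bounding_rect(mask)
            area = box.area if box else 0
            if prev_mask is not None:
                assert (mask <= prev_mask).all()
                assert area <= prev_area
            prev_mask, prev_area = mask, area


class TestMinBoundingRect:
    def test_point_mask(self):
        mask = np.zeros((6, 6), dtype=int)
        mask[3, 2] = 1
        assert min_bounding_rect(mask) == BoundingBox(x=2, y=3, w=1, h=1)

    def test_full_mask(self):
        assert min_bounding_rect(np.ones((10, 10))) == BoundingBox(0, 0, 10, 10)

    def test_two_corner_pixels(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[1, 1] = mask[4, 6] = 1
        assert min_bounding_rect(mask) == BoundingBox(x=1, y=1, w=6, h=4)

    def test_empty_mask_returns_none(self):
        assert min_bounding_rect(np.zeros((5, 5))) is None

    def test_oracle_equivalence_200_random_masks(self, rng):
        """Exact agreement with the brute-force min/max scan, all densities."""
        for i in range(200):
            h, w = rng.integers(8, 65, size=2)
            density = rng.random()
            mask = (rng.random((h, w)) < density).astype(int)
            box = min_bounding_rect(mask)
            assert box == brute_force_box(mask)
            if box is not None:
                ys, xs = np.nonzero(mask)
                assert (box.y <= ys).all() and (ys < box.y + box.h).all()
                assert (box.x <= xs).all() and (xs < box.x + box.w).all()


class TestCropAndResize:
    def test_full_image_identity(self, rng):
        img = rng.random((12, 10, 3))
        out = crop_and_resize(img, BoundingBox(0, 0, 10, 12), (12, 10))
        np.testing.assert_array_equal(out, img)

    def test_output_is_target_size(self, rng):
        img = rng.random((64, 64, 3))
        out = crop_and_resize(img, BoundingBox(5, 7, 20, 11), (224, 224))
        assert out.shape == (224, 224, 3)

    def test_constant_region_stays_constant(self):
        img = np.full((16, 16, 3), 0.42)
        out = crop_and_resize(img, BoundingBox(3, 3, 2, 2), (8, 8))
        np.testing.assert_allclose(out, 0.42)

    def test_box_outside_bounds_raises(self):
        with pytest.raises(ValueError):
            crop_and_resize(np.zeros((8, 8, 3)), BoundingBox(5, 5, 6, 2), (8, 8))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 0, 3)


class TestAttentionCropDataset:
    def test_theta_255_is_noop(self, toy_data, trained_toy_clf):
        dataset, _ = toy_data
        sub = type(dataset)(records=dataset.records[:6],
                            class_names=dataset.class_names)
        out, prov = attention_crop_dataset(trained_toy_clf.net_, sub, theta=255.0)
        assert len(out) == len(sub) and prov == []

    def test_crops_inherit_labels_and_grow_dataset(self, toy_data, trained_toy_clf):
        dataset, _ = toy_data
        sub = type(dataset)(records=dataset.records[:10],
                            class_names=dataset.class_names)
        out, prov = attention_crop_dataset(trained_toy_clf.net_, sub, theta=128.0)
        n_pos = sum(1 for r in sub.records if r.labels.sum() > 0)
        assert len(prov) <= n_pos
        assert len(out) == len(sub) + len(prov)
        by_id = {r.image_id: r for r in out.records}
        for p in prov:
            crop = by_id[p["source_id"] + "_crop"]
            np.testing.assert_array_equal(crop.labels, by_id[p["source_id"]].labels)
            assert crop.image.shape == by_id[p["source_id"]].image.shape


class TestClassicAugment:
    DEGENERATE = {"brightness": 1.0, "gamma": (1.0, 1.0), "saturation": 1.0,
                  "rotation_deg": 0.0, "crop_keep_frac": 1.0, "flip_prob": 0.0}

    def test_degenerate_config_is_identity(self, rng):
        img = rng.random((16, 16, 3))
        out = classic_augment(img, np.random.default_rng(0), self.DEGENERATE)
        np.testing.assert_allclose(out, img)

    def test_flip_is_involution(self, rng):
        img = rng.random((16, 16, 3))
        ops = dict(self.DEGENERATE, flip_prob=1.0)
        once = classic_augment(img, np.random.default_rng(0), ops)
        twice = classic_augment(once, np.random.default_rng(0), ops)
        np.testing.assert_allclose(twice, img)

    def test_gamma_one_is_fixed_point(self, rng):
        img = rng.random((16, 16, 3))
        ops = dict(self.DEGENERATE, gamma=(1.0, 1.0))
        np.testing.assert_allclose(classic_augment(img, np.random.default_rng(1), ops), img)

    def test_deterministic_given_rng_state(self, rng):
        img = rng.random((16, 16, 3))
        a = classic_augment(img, np.random.default_rng(7))
        b = classic_augment(img, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        assert a.shape == img.shape

    def test_unknown_key_rejected(self, rng):
        with pytest.raises(ValueError):
            classic_augment(rng.random((8, 8, 3)), np.random.default_rng(0),
                            {"mixup": 0.2})
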