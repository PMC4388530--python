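"""Particle detection and the seven shape characteristics."""

import numpy as np
import pytest

from bactrack import detect_particles, measure_features
from bactrack.diffstack import SumDiffImage


def norm_image(arr):
    return SumDiffImage(values=np.asarray(arr, np.uint8), source_index=0,
                        normalized=True)


def brute_force_features(mask):
    """Independent oracle: direct double loop over member pixels."""
    pts = [(x, y) for y in range(mask.shape[0])
           for x in range(mask.shape[1]) if mask[y, x]]
    area = len(pts)
    cm_x = sum(p[0] for p in pts) / area
    cm_y = sum(p[1] for p in pts) / area
    perimeter = 0
    for x, y in pts:
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if not (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                    and mask[ny, nx]):
                perimeter += 1
    mu20 = sum((x - cm_x) ** 2 for x, _ in pts)
    mu02 = sum((y - cm_y) ** 2 for _, y in pts)
    mu11 = sum((x - cm_x) * -(y - cm_y) for x, y in pts)
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - (mu02))
    return area, cm_x, cm_y, perimeter, np.degrees(theta)


class TestDetect:
    def test_all_zero_image_yields_nothing(self):
        assert detect_particles(norm_image(np.zeros((10, 10)))) == []

    def test_single_block(self):
        img = np.zeros((12, 12))
        img[3:8, 4:9] = 255
        masks = detect_particles(norm_image(img), threshold=128, min_area=4)
        assert len(masks) == 1
        assert masks[0].sum() == 25

    def test_two_blocks_and_a_speck(self):
        img = np.zeros((12, 20))
        img[2:5, 2:5] = 255
        img[2:5, 10:13] = 255
        img[9, 17] = 255
        masks = detect_particles(norm_image(img), threshold=128, min_area=4)
        assert len(masks) == 2
        assert all(m.sum() == 9 for m in masks)

    def test_diagonal_pixels_are_one_component(self):
        img = np.zeros((8, 8))
        img[2, 2] = img[3, 3] = img[4, 4] = 255
        masks = detect_particles(norm_image(img), threshold=128, min_area=1)
        assert len(masks) == 1

    def test_requires_normalized_input_and_valid_threshold(self):
        raw = SumDiffImage(values=np.ones((4, 4), np.int32), source_index=0)
        with pytest.raises(ValueError):
            detect_particles(raw)
        with pytest.raises(ValueError):
            detect_particles(norm_image(np.full((4, 4), 9)), threshold=0)


class TestMeasure:
    def test_5x5_block(self):
        mask = np.zeros((30, 30), bool)
        mask[10:15, 10:15] = True
        rec = measure_features(mask)
        assert rec.area == 25
        assert (rec.cm_x, rec.cm_y) == (12.0, 12.0)
        assert rec.perimeter == 20
        assert rec.length == rec.width == 5.0

    def test_horizontal_rectangle(self):
        mask = np.zeros((10, 20), bool)
        mask[4:6, 5:15] = True
        rec = measure_features(mask)
        assert rec.orientation == pytest.approx(0.0)
        assert rec.length == pytest.approx(10.0)
        assert rec.width == pytest.approx(2.0)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        rec = measure_features(mask)
        assert rec.area == 1
        assert rec.length == rec.width == 1.0
        assert rec.perimeter == 4

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_features(np.zeros((4, 4), bool))

    def test_agrees_with_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            mask = np.zeros((14, 14), bool)
            mask[3:11, 3:11] = rng.random((8, 8)) < 0.6
            if not mask.any():
                continue
            rec = measure_features(mask)
            area, cm_x, cm_y, perim, _ = brute_force_features(mask)
            assert rec.area == area
            assert rec.cm_x == pytest.approx(cm_x)
            assert rec.cm_y == pytest.approx(cm_y)
            assert rec.perimeter == perim

    def test_translation_equivariance(self, rng):
        base = np.zeros((40, 40), bool)
        base[5:12, 6:16] = rng.random((7, 10)) < 0.7
        base[8, 10] = True
        rec0 = measure_features(base)
        shifted = np.roll(np.roll(base, 13, axis=0), 9, axis=1)
        rec1 = measure_features(shifted)
        assert rec1.cm_x - rec0.cm_x == pytest.approx(9.0)
        assert rec1.cm_y - rec0.cm_y == pytest.approx(13.0)
        for attr in ("area", "perimeter", "orientation", "length", "width"):
            assert getattr(rec1, attr) == pytest.approx(getattr(rec0, attr))

    def test_90_degree_rotation(self, rng):
        mask = np.zeros((20, 20), bool)
        mask[4:7, 3:15] = rng.random((3, 12)) < 0.8
        mask[5, 3:15] = True
        rec0 = measure_features(mask)
        rec90 = measure_features(np.rot90(mask))
        assert rec90.area == rec0.area
        assert rec90.perimeter == rec0.perimeter
        assert rec90.length == pytest.approx(rec0.length)
        assert rec90.width == pytest.approx(rec0.width)
        delta = (rec90.orientation - rec0.orientation) % 180.0
        assert min(delta, 180.0 - delta) == pytest.approx(90.0, abs=1e-6)

    def test_border_touching_flagged(self):
        mask = np.zeros((6, 6), bool)
        mask[0:3, 2:5] = True
        assert measure_features(mask).touches_border
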