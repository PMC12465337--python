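"""Segmentation, mask ingestion, soma labelling and mean fluorescence."""

import itertools

import numpy as np
import pytest

from neurocult import (
    CultureSpec,
    FieldImage,
    SegmentationMasks,
    ShapeMismatchError,
    generate_timecourse,
    ingest_masks,
    label_somata,
    mean_fluorescence,
    pixel_edge_perimeter,
    rescale_minmax,
    segment,
)
from neurocult.segmentation import dice_coefficient

from oracles import boundary_edge_count, flood_fill_label, masked_mean_loop


class TestSegment:
    def test_recovers_discs_and_curves(self, disc_and_curves_image):
        image, true_soma, true_neurite = disc_and_curves_image
        masks = segment(rescale_minmax(image))
        assert dice_coefficient(masks.soma_mask, true_soma) >= 0.9
        assert dice_coefficient(masks.neurite_mask, true_neurite) >= 0.8

    def test_blank_image_gives_empty_masks(self):
        masks = segment(FieldImage(pixels=np.zeros((64, 64)), bit_depth=32))
        assert not masks.soma_mask.any() and not masks.neurite_mask.any()

    def test_disc_only_image_has_empty_neurite_mask(self):
        rr, cc = np.indices((96, 96))
        img = np.full((96, 96), 20.0)
        img[(rr - 48) ** 2 + (cc - 48) ** 2 <= 64] = 1000.0
        masks = segment(FieldImage(pixels=img, bit_depth=32))
        assert masks.soma_mask.sum() > 100
        assert masks.neurite_mask.sum() < 20  # rim residue at most

    def test_dice_thresholds_on_generator_grid(self):
        """Mean Dice over a seeded default-spec grid clears 0.9 soma /
        0.8 neurite, with a per-frame floor of 0.8."""
        soma_scores, neurite_scores = [], []
        for seed in range(1, 6):
            images, truth = generate_timecourse(CultureSpec(seed=seed, n_days=3))
            for d, img in enumerate(images):
                masks = segment(rescale_minmax(img))
                soma_scores.append(dice_coefficient(masks.soma_mask, truth.soma_masks[d]))
                neurite_scores.append(dice_coefficient(masks.neurite_mask, truth.neurite_masks[d]))
        assert np.mean(soma_scores) >= 0.9 and min(soma_scores) >= 0.8
        assert np.mean(neurite_scores) >= 0.8 and min(neurite_scores) >= 0.8


class TestIngestMasks:
    def test_identity_round_trip(self):
        img = FieldImage(pixels=np.zeros((8, 8)), bit_depth=32)
        soma = np.zeros((8, 8), dtype=np.uint8)
        soma[:2, :2] = 255
        neurite = np.zeros((8, 8), dtype=np.uint8)
        neurite[5:, 5:] = 255
        masks = ingest_masks(soma, neurite, img)
        assert masks.source == "external"
        assert np.array_equal(masks.soma_mask, soma > 0)
        assert np.array_equal(masks.neurite_mask, neurite > 0)

    def test_overlap_resolved_soma_priority(self):
        img = FieldImage(pixels=np.zeros((4, 4)), bit_depth=32)
        both = np.ones((4, 4))
        masks = ingest_masks(both, both, img)
        assert masks.soma_mask.all() and not masks.neurite_mask.any()

    def test_nonbinary_values_binarized(self):
        img = FieldImage(pixels=np.zeros((1, 3)), bit_depth=32)
        masks = ingest_masks(np.array([[0, 128, 255]]), np.zeros((1, 3)), img)
        assert masks.soma_mask.tolist() == [[False, True, True]]

    def test_shape_mismatch_reports_both_shapes(self):
        img = FieldImage(pixels=np.zeros((4, 4)), bit_depth=32)
        with pytest.raises(ShapeMismatchError, match=r"\(2, 2\).*\(4, 4\)"):
            ingest_masks(np.ones((2, 2)), np.ones((4, 4)), img)


class TestLabelSomata:
    @staticmethod
    def _masks(soma):
        return SegmentationMasks(soma, np.zeros_like(soma, dtype=bool))

    def test_two_disjoint_squares(self):
        soma = np.zeros((12, 12), dtype=bool)
        soma[1:6, 1:6] = True
        soma[7:12, 7:12] = True
        objs = label_somata(self._masks(soma))
        assert objs.object_count == 2
        assert sorted(objs.areas.tolist()) == [25, 25]

    def test_diagonal_touch_is_one_object(self):
        soma = np.zeros((8, 8), dtype=bool)
        soma[0:3, 0:3] = True
        soma[3:6, 3:6] = True
        assert label_somata(self._masks(soma)).object_count == 1

    def test_empty_mask_zero_objects(self):
        objs = label_somata(self._masks(np.zeros((5, 5), dtype=bool)))
        assert objs.object_count == 0 and objs.total_area == 0

    def test_total_area_equals_mask_pixels(self, default_timecourse):
        _, _, truth = default_timecourse
        objs = label_somata(self._masks(truth.soma_masks[0]))
        assert objs.total_area == truth.soma_masks[0].sum()

    def test_matches_flood_fill_oracle_exhaustively_on_3x3(self):
        """All 512 binary 3x3 grids: object count matches brute force."""
        for bits in range(512):
            mask = np.array([(bits >> k) & 1 for k in range(9)], dtype=bool).reshape(3, 3)
            _, n = flood_fill_label(mask)
            assert label_somata(self._masks(mask)).object_count == n

    def test_random_blobs_match_oracle(self, rng):
        for _ in range(25):
            mask = rng.random((16, 16)) < 0.4
            objs = label_somata(self._masks(mask))
            labels, n = flood_fill_label(mask)
            assert objs.object_count == n
            assert objs.total_perimeter == boundary_edge_count(mask)
            oracle_areas = sorted(np.bincount(labels.ravel())[1:].tolist())
            assert sorted(objs.areas.astype(int).tolist()) == oracle_areas


class TestPerimeter:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            (np.ones((1, 1), dtype=bool), 4),
            (np.ones((10, 10), dtype=bool), 40),
            (np.ones((10, 20), dtype=bool), 60),
        ],
    )
    def test_rectangles(self, mask, expected):
        assert pixel_edge_perimeter(mask) == expected


class TestMeanFluorescence:
    def test_uniform_image(self):
        img = FieldImage(pixels=np.full((6, 6), 7.0), bit_depth=32)
        soma = np.zeros((6, 6), dtype=bool)
        soma[0, 0] = True
        assert mean_fluorescence(img, SegmentationMasks(soma, np.zeros_like(soma))) == 7.0

    def test_only_masked_pixels_counted(self):
        px = np.zeros((4, 4))
        px[:2] = 10.0
        soma = np.zeros((4, 4), dtype=bool)
        soma[:2] = True
        img = FieldImage(pixels=px, bit_depth=32)
        assert mean_fluorescence(img, SegmentationMasks(soma, np.zeros_like(soma))) == 10.0

    def test_invariant_to_outside_intensities(self, rng):
        soma = rng.random((16, 16)) < 0.3
        px = rng.uniform(0, 100, (16, 16))
        img_a = FieldImage(pixels=px, bit_depth=32)
        px_b = px.copy()
        px_b[~soma] = 9999.0
        img_b = FieldImage(pixels=px_b, bit_depth=32)
        masks = SegmentationMasks(soma, np.zeros_like(soma))
        assert mean_fluorescence(img_a, masks) == mean_fluorescence(img_b, masks)

    def test_matches_loop_oracle(self, rng):
        px = rng.uniform(0, 50, (12, 12))
        soma = rng.random((12, 12)) < 0.5
        neur = (rng.random((12, 12)) < 0.3) & ~soma
        img = FieldImage(pixels=px, bit_depth=32)
        got = mean_fluorescence(img, SegmentationMasks(soma, neur))
        assert got == pytest.approx(masked_mean_loop(px, soma | neur), abs=1e-12)

    def test_empty_union_returns_zero(self):
        img = FieldImage(pixels=np.ones((4, 4)), bit_depth=32)
        z = np.zeros((4, 4), dtype=bool)
        assert mean_fluorescence(img, SegmentationMasks(z, z.copy())) == 0.0
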