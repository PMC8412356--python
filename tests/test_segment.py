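"""Segmentation: thresholding, clump splitting, measurement oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import make_disk_image
from scpnscreen.segment import (FieldImage, SegmentationParams, binarize_nuclei,
                                candidates_to_frame, find_nuclei,
                                measure_candidates, refine_and_filter_labels,
                                split_and_label)

PARAMS = SegmentationParams()


class TestBinarize:
    def test_blank_field_empty_mask(self):
        img = FieldImage(channels={"hoechst": np.zeros((64, 64))}, pixel_scale=0.65)
        assert not binarize_nuclei(img, PARAMS).any()
        assert find_nuclei(img, PARAMS) == []

    def test_uniform_disk_mask_is_the_disk(self):
        img = make_disk_image([(40, 40)], [4.0], [1000.0])
        mask = binarize_nuclei(img, PARAMS)
        assert np.array_equal(mask, img.channels["hoechst"] > 0)

    def test_missing_hoechst_channel(self):
        img = FieldImage(channels={"ch488": np.zeros((8, 8))}, pixel_scale=0.65)
        with pytest.raises(ValueError, match="hoechst"):
            binarize_nuclei(img, PARAMS)

    def test_mismatched_channel_dims_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            FieldImage(channels={"hoechst": np.zeros((8, 8)),
                                 "ch488": np.zeros((9, 8))}, pixel_scale=0.65)


class TestSplitAndLabel:
    def test_single_disk_single_label(self):
        img = make_disk_image([(40, 40)], [4.0], [1000.0])
        labels = split_and_label(binarize_nuclei(img, PARAMS), img, PARAMS)
        assert labels.max() == 1

    def test_overlapping_pair_split_into_two(self):
        """Two 4 um-radius nuclei with centers 7 um apart yield 2 labels."""
        img = make_disk_image([(38, 40), (45, 40)], [4.0, 4.0], [1000.0, 1000.0])
        labels = split_and_label(binarize_nuclei(img, PARAMS), img, PARAMS)
        assert labels.max() == 2

    def test_small_fragment_discarded(self):
        """An 8 um^2 fragment falls below the 10 um^2 area floor."""
        r = np.sqrt(8.0 / np.pi)
        img = make_disk_image([(40, 40)], [r], [1000.0])
        mask = binarize_nuclei(img, PARAMS)
        area = mask.sum() * 0.65 ** 2
        assert area < 10.0
        labels = split_and_label(mask, img, PARAMS)
        assert labels.max() == 0

    def test_labels_are_raster_ordered(self):
        img = make_disk_image([(60, 20), (20, 60)], [4.0, 4.0], [1000.0, 800.0])
        labels = split_and_label(binarize_nuclei(img, PARAMS), img, PARAMS)
        cands = measure_candidates(labels, img)
        assert cands[0].y_px < cands[1].y_px  # top region labeled first


class TestMeasure:
    def test_uniform_marker_mean_is_exact(self):
        img = make_disk_image([(40, 40)], [4.0], [1000.0], marker_value=321.0)
        labels = split_and_label(binarize_nuclei(img, PARAMS), img, PARAMS)
        (cand,) = measure_candidates(labels, img)
        assert cand.mean_intensity["ch488"] == pytest.approx(321.0)
        assert cand.mean_intensity["hoechst"] == pytest.approx(1000.0)

    def test_area_is_pixel_count_times_scale_squared(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels.flat[:120] = 1  # 120 pixels at 0.65 um/px -> 50.7 um^2
        img = FieldImage(channels={"hoechst": np.ones((30, 30))}, pixel_scale=0.65)
        (cand,) = measure_candidates(labels, img)
        assert cand.area_um2 == pytest.approx(120 * 0.65 ** 2)
        assert cand.area_um2 == pytest.approx(50.7)

    def test_empty_label_set(self):
        img = FieldImage(channels={"hoechst": np.zeros((16, 16))}, pixel_scale=0.65)
        assert measure_candidates(np.zeros((16, 16), np.int32), img) == []

    def test_constant_offset_shifts_mean_exactly(self):
        img = make_disk_image([(40, 40)], [4.0], [1000.0], marker_value=100.0)
        labels = split_and_label(binarize_nuclei(img, PARAMS), img, PARAMS)
        (c0,) = measure_candidates(labels, img)
        shifted = FieldImage(
            channels={"hoechst": img.channels["hoechst"],
                      "ch488": img.channels["ch488"] + 57.0},
            pixel_scale=img.pixel_scale)
        (c1,) = measure_candidates(labels, shifted)
        assert c1.mean_intensity["ch488"] - c0.mean_intensity["ch488"] == (
            pytest.approx(57.0))


class TestOnSyntheticFields:
    def test_mask_overlaps_truth_footprints(self, rendered_field):
        """Foreground IoU with the union of true footprints is >= 0.8."""
        cells, _, image = rendered_field
        mask = binarize_nuclei(image, PARAMS)
        h, w = image.shape
        yy, xx = np.mgrid[0:h, 0:w]
        truth = np.zeros((h, w), bool)
        scale = image.pixel_scale
        for _, c in cells.iterrows():
            r_px = np.sqrt(c.area_um2 / np.pi) / scale
            truth |= ((xx - c.x_px) ** 2 + (yy - c.y_px) ** 2) <= r_px ** 2
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.8

    def test_nontouching_split_equals_connected_components(self, default_design):
        """With no touching nuclei, splitting adds nothing beyond labeling."""
        from scpnscreen.simulate import (NULL_EFFECT, generate_field,
                                         primary_neuron_model)

        design, _, _ = default_design
        design = design.model_copy(update={"clump_fraction": 0.0,
                                           "min_spacing_um": 14.0})
        # no fused-doublet class: those are meant to be split, not preserved
        model = primary_neuron_model(nonviable_mix=(0.7, 0.0, 0.3),
                                     density=150)
        rng = np.random.default_rng(21)
        _, imgs = generate_field(model, NULL_EFFECT, design, rng)
        image = FieldImage(channels=imgs, pixel_scale=0.65)
        mask = binarize_nuclei(image, PARAMS)
        got = split_and_label(mask, image, PARAMS)
        cc, _ = ndi.label(mask, structure=np.ones((3, 3), bool))
        oracle = refine_and_filter_labels(cc, image, PARAMS)
        assert np.array_equal(got, oracle)

    def test_detection_precision_and_recall(self, rendered_field):
        from scipy.spatial import cKDTree

        cells, _, image = rendered_field
        cands = find_nuclei(image, PARAMS)
        scale = image.pixel_scale
        tree = cKDTree(cells[["x_px", "y_px"]].to_numpy() * scale)
        d, idx = tree.query(np.array([[c.x_px, c.y_px] for c in cands]) * scale)
        matched: set[int] = set()
        tp = sum(1 for dd, ti in zip(d, idx)
                 if dd <= 2.0 and ti not in matched and not matched.add(ti))
        assert tp / len(cands) >= 0.95  # precision
        assert tp / len(cells) >= 0.90  # recall (clumped pairs included)

    def test_candidate_count_monotone_in_min_area_and_contrast(self, rendered_field):
        _, _, image = rendered_field
        counts_area = [len(find_nuclei(image, PARAMS.model_copy(
            update={"min_area": a}))) for a in (10.0, 25.0, 40.0)]
        assert counts_area[0] >= counts_area[1] >= counts_area[2]
        counts_ctr = [len(find_nuclei(image, PARAMS.model_copy(
            update={"contrast": c}))) for c in (0.05, 0.2, 0.4)]
        assert counts_ctr[0] >= counts_ctr[1] >= counts_ctr[2]

    def test_determinism(self, rendered_field):
        _, _, image = rendered_field
        a = find_nuclei(image, PARAMS)
        b = find_nuclei(image, PARAMS)
        assert candidates_to_frame(a).equals(candidates_to_frame(b))
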