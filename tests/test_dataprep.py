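"""Annotation pipeline: mask splitting, COCO/VOC conversions, cleaning."""

import json

import numpy as np
import pytest

from phenonas import dataprep as dp
from phenonas import synthetic as syn


def make_annotation(label, genotype="col-0", image_id="p0", declared=None):
    return dp.annotate_plant(image_id, f"{image_id}.png", label, genotype, declared)


class TestSplitLabelImage:
    def test_all_background_gives_empty_list(self):
        assert dp.split_label_image(np.zeros((8, 8), dtype=np.uint8)) == []

    def test_two_color_toy_image(self):
        """Brute-force oracle on a 5x5 image: color A at (0,0),(0,1), color B
        at (3,3) -> areas 2 and 1, half-open bboxes (0,0,2,1) and (3,3,4,4)."""
        label = np.zeros((5, 5), dtype=np.uint8)
        label[0, 0] = label[0, 1] = 7
        label[3, 3] = 9
        a, b = dp.split_label_image(label)
        assert (a.area_px, a.bbox) == (2, (0, 0, 2, 1))
        assert (b.area_px, b.bbox) == (1, (3, 3, 4, 4))

    def test_instance_order_is_first_pixel_raster_order(self):
        label = np.zeros((4, 4), dtype=np.uint8)
        label[2, 0] = 1  # value 1 appears later in raster order
        label[0, 3] = 5
        first, second = dp.split_label_image(label)
        assert first.mask[0, 3] and second.mask[2, 0]

    def test_masks_disjoint_and_area_conserved(self, dataset50):
        root, rows, annotations = dataset50
        plant = annotations[0]
        total = np.zeros((plant.height, plant.width), dtype=int)
        for inst in plant.leaf_instances:
            total += inst.mask.astype(int)
        assert total.max() <= 1
        label = syn.load_label_png(root / f"{rows[0]['image_id']}_label.png")
        assert total.sum() == int((label != 0).sum())

    def test_rendered_k_leaf_scene_gives_k_instances(self):
        leaves = tuple(
            syn.LeafShape((16.0 + 30.0 * i, 16.0), (6.0, 4.0), 0.0, i) for i in range(3)
        )
        _, label = syn.render_scene(syn.RosetteScene("col-0", leaves, 96))
        assert len(dp.split_label_image(label)) == 3

    def test_antialiased_truecolor_rejected_with_color_names(self):
        rng = np.random.default_rng(0)
        noisy = rng.integers(1, 255, size=(32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="#"):
            dp.split_label_image(noisy)

    def test_clean_truecolor_accepted(self):
        rgb = np.zeros((6, 6, 3), dtype=np.uint8)
        rgb[1:3, 1:3] = (255, 0, 0)
        rgb[4, 4] = (0, 255, 0)
        instances = dp.split_label_image(rgb)
        assert [i.area_px for i in instances] == [4, 1]


class TestCoco:
    def test_bbox_convention_and_round_trip(self):
        label = np.zeros((5, 5), dtype=np.uint8)
        label[0, 0] = label[0, 1] = 1
        doc = dp.to_coco([make_annotation(label)])
        assert doc["annotations"][0]["bbox"] == [0, 0, 2, 1]
        assert doc["categories"] == [{"id": 1, "name": "leaf", "supercategory": "plant"}]
        json.dumps(doc)  # serializable

    def test_three_leaves_share_one_image_id(self, dataset50):
        _, _, annotations = dataset50
        plant = annotations[0]
        doc = dp.to_coco([plant])
        assert len(doc["annotations"]) == plant.leaf_count
        assert {a["image_id"] for a in doc["annotations"]} == {1}

    def test_area_sum_matches_label_foreground(self, dataset50):
        root, rows, annotations = dataset50
        doc = dp.to_coco(annotations)
        by_image = {}
        for ann in doc["annotations"]:
            by_image[ann["image_id"]] = by_image.get(ann["image_id"], 0) + ann["area"]
        for image in doc["images"]:
            label = syn.load_label_png(root / f"{image['plant_id']}_label.png")
            assert by_image.get(image["id"], 0) == int((label != 0).sum())

    def test_duplicate_image_ids_rejected(self):
        label = np.zeros((4, 4), dtype=np.uint8)
        label[0, 0] = 1
        ann = make_annotation(label)
        with pytest.raises(ValueError, match="duplicate"):
            dp.to_coco([ann, ann])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dp.to_coco([])


class TestVoc:
    def test_half_open_to_one_based_inclusive(self, tmp_path):
        label = np.zeros((5, 5), dtype=np.uint8)
        label[0, 0] = label[0, 1] = 1
        doc = dp.to_coco([make_annotation(label)])
        (path,) = dp.coco_to_voc(doc, tmp_path)
        text = path.read_text()
        assert "<xmin>1</xmin>" in text and "<ymin>1</ymin>" in text
        assert "<xmax>2</xmax>" in text and "<ymax>1</ymax>" in text

    def test_round_trip_preserves_everything(self, dataset50, tmp_path):
        _, _, annotations = dataset50
        subset = annotations[:5]
        paths = dp.coco_to_voc(dp.to_coco(subset), tmp_path)
        for plant, path in zip(subset, paths):
            back = dp.read_voc(path)
            assert back.image_id == plant.image_id
            assert back.genotype == plant.genotype
            assert back.leaf_count == plant.leaf_count
            assert [i.bbox for i in back.leaf_instances] == [i.bbox for i in plant.leaf_instances]
            assert [i.area_px for i in back.leaf_instances] == [i.area_px for i in plant.leaf_instances]

    def test_missing_genotype_rejected(self, tmp_path):
        label = np.zeros((4, 4), dtype=np.uint8)
        label[0, 0] = 1
        doc = dp.to_coco([make_annotation(label)])
        doc["images"][0]["genotype"] = None
        with pytest.raises(ValueError, match="genotype"):
            dp.coco_to_voc(doc, tmp_path)

    def test_missing_area_element_rejected(self, tmp_path):
        label = np.zeros((4, 4), dtype=np.uint8)
        label[0, 0] = 1
        (path,) = dp.coco_to_voc(dp.to_coco([make_annotation(label)]), tmp_path)
        path.write_text(path.read_text().replace("<area_px>1</area_px>", ""))
        with pytest.raises(ValueError, match="area_px"):
            dp.read_voc(path)


class TestClean:
    def test_kept_iff_counts_match(self):
        label = np.zeros((6, 6), dtype=np.uint8)
        label[0, 0] = 1
        label[3, 3] = 2
        good = make_annotation(label, image_id="good")
        bad = make_annotation(label, image_id="bad")
        manifest = {"good": 2, "bad": 3}
        kept, dropped = dp.clean([good, bad], manifest)
        assert [a.image_id for a in kept] == ["good"]
        assert dropped == [{"image_id": "bad", "derived": 2, "declared": 3}]

    def test_corrupted_plant_is_the_only_drop(self, dataset50):
        """Deleting one leaf color from one label image drops exactly that
        plant under the leaf-count consistency rule."""
        root, rows, annotations = dataset50
        victim = annotations[3]
        label = syn.load_label_png(root / f"{victim.image_id}_label.png")
        corrupted = label.copy()
        corrupted[corrupted == 1] = 0
        bad = dp.annotate_plant(victim.image_id, victim.image_path, corrupted,
                                victim.genotype, victim.declared_leaf_count)
        cohort = [bad if a.image_id == victim.image_id else a for a in annotations]
        kept, dropped = dp.clean(cohort, rows)
        assert [d["image_id"] for d in dropped] == [victim.image_id]
        assert len(kept) == len(annotations) - 1

    def test_idempotent(self, dataset50):
        _, rows, annotations = dataset50
        kept1, _ = dp.clean(annotations, rows)
        kept2, dropped2 = dp.clean(kept1, rows)
        assert dropped2 == []
        assert all(a is b for a, b in zip(kept1, kept2)) and len(kept1) == len(kept2)

    def test_missing_manifest_row_errors(self):
        label = np.zeros((4, 4), dtype=np.uint8)
        label[0, 0] = 1
        with pytest.raises(KeyError):
            dp.clean([make_annotation(label, image_id="orphan")], {})


class TestTrainingArrays:
    def test_shapes_and_ranges(self, dataset50, arrays50):
        _, _, annotations = dataset50
        x, y_cls, y_cnt, y_area = arrays50
        assert x.shape == (len(annotations), 28, 28, 3)
        assert x.min() >= 0 and x.max() <= 1
        assert y_cls.dtype == np.int64 and set(y_cls) <= set(range(5))
        assert y_cnt.dtype == np.float32
        assert ((0 < y_area) & (y_area < 1)).all()

    def test_constant_image_survives_resize(self, tmp_path):
        from PIL import Image

        rgb = np.full((64, 64, 3), 77, dtype=np.uint8)
        Image.fromarray(rgb).save(tmp_path / "c.png")
        label = np.zeros((64, 64), dtype=np.uint8)
        label[0, 0] = 1
        ann = dp.annotate_plant("c", tmp_path / "c.png", label, "col-0")
        x, _, _, _ = dp.build_training_arrays([ann])
        assert np.allclose(x, 77 / 255.0)

    def test_half_canvas_foreground_normalizes_to_half(self, tmp_path):
        from PIL import Image

        label = np.zeros((32, 32), dtype=np.uint8)
        label[:16, :] = 1  # exactly half the canvas
        Image.fromarray(np.zeros((32, 32, 3), dtype=np.uint8)).save(tmp_path / "h.png")
        ann = dp.annotate_plant("h", tmp_path / "h.png", label, "col-0")
        _, _, _, areas = dp.build_training_arrays([ann])
        assert areas[0] == pytest.approx(0.5)
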