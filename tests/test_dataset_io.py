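"""Labelme/COCO conversion, mask encodings, augmentation, splitting."""

import json

import numpy as np
import pytest

from podmetrics.dataset_io import (
    AugmentationSpec,
    LabeledInstance,
    apply_augmentation,
    coco_to_instances,
    load_predictions,
    polygon_to_mask,
    read_labelme,
    rle_decode,
    rle_encode,
    split_dataset,
    to_coco,
    to_labelme,
)


def make_instance(polygon, label="pod", image="a.png", h=100, w=100):
    return LabeledInstance(label, np.asarray(polygon, float), image, h, w)


@pytest.fixture
def labelme_file(tmp_path):
    doc = {
        "imagePath": "a.png",
        "imageHeight": 100,
        "imageWidth": 120,
        "shapes": [
            {"label": "pod", "shape_type": "polygon",
             "points": [[10, 10], [40, 12], [38, 30], [12, 28]]},
            {"label": "coin", "shape_type": "polygon",
             "points": [[60, 60], [80, 60], [80, 80], [60, 80]]},
            {"label": "ignore-me", "shape_type": "rectangle",
             "points": [[0, 0], [5, 5]]},
        ],
    }
    p = tmp_path / "a.json"
    p.write_text(json.dumps(doc))
    return p


class TestLabelme:
    def test_polygons_read_and_rectangle_skipped(self, labelme_file):
        instances = read_labelme(labelme_file)
        assert [i.label for i in instances] == ["pod", "coin"]
        assert len(instances[0].polygon) == 4

    def test_roundtrip_preserves_labels_and_points(self, labelme_file, tmp_path):
        instances = read_labelme(labelme_file)
        doc = to_labelme(instances, "a.png", 100, 120)
        p2 = tmp_path / "b.json"
        p2.write_text(json.dumps(doc))
        again = read_labelme(p2)
        assert [i.label for i in again] == [i.label for i in instances]
        for a, b in zip(again, instances):
            assert np.allclose(a.polygon, b.polygon)

    def test_empty_shapes(self, tmp_path):
        p = tmp_path / "e.json"
        p.write_text(json.dumps({"imageHeight": 10, "imageWidth": 10, "shapes": []}))
        assert read_labelme(p) == []

    def test_malformed_json_and_missing_size(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_labelme(bad)
        nosize = tmp_path / "nosize.json"
        nosize.write_text(json.dumps({"shapes": []}))
        with pytest.raises(ValueError, match="imageHeight"):
            read_labelme(nosize)


class TestToCoco:
    def test_triangle_area_and_bbox(self):
        inst = make_instance([(0, 0), (4, 0), (0, 3)])
        doc = to_coco([inst])
        (ann,) = doc["annotations"]
        assert ann["area"] == pytest.approx(6.0)
        assert ann["bbox"] == [0.0, 0.0, 4.0, 3.0]
        assert ann["iscrowd"] == 0

    def test_empty_dataset_is_valid(self):
        doc = to_coco([])
        assert doc["annotations"] == [] and doc["images"] == []
        assert doc["categories"][0]["name"] == "pod"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="weed"):
            to_coco([make_instance([(0, 0), (1, 0), (0, 1)], label="weed")])

    def test_two_image_doc_ids_and_shoelace_areas(self):
        rng = np.random.default_rng(0)
        instances = []
        for img in ("b.png", "a.png"):
            for _ in range(2):
                ang = np.sort(rng.uniform(0, 2 * np.pi, 8))
                pts = np.column_stack(
                    [30 + 10 * np.cos(ang), 30 + 10 * np.sin(ang)]
                )
                instances.append(make_instance(pts, image=img))
        doc = to_coco(instances)
        assert [im["file_name"] for im in doc["images"]] == ["a.png", "b.png"]
        assert [im["id"] for im in doc["images"]] == [1, 2]
        assert [a["id"] for a in doc["annotations"]] == [1, 2, 3, 4]
        for ann in doc["annotations"]:
            pts = np.asarray(ann["segmentation"][0]).reshape(-1, 2)
            x, y = pts[:, 0], pts[:, 1]
            shoelace = abs(
                np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
            ) / 2
            assert ann["area"] == pytest.approx(shoelace)
        # annotations reference existing images
        ids = {im["id"] for im in doc["images"]}
        assert all(a["image_id"] in ids for a in doc["annotations"])

    def test_labelme_coco_roundtrip_exact(self, labelme_file):
        instances = read_labelme(labelme_file)
        doc = to_coco(instances, ["pod", "coin"])
        back = coco_to_instances(doc)
        assert len(back) == len(instances)
        for a, b in zip(back, instances):
            assert len(a.polygon) == len(b.polygon)
            assert a.area == pytest.approx(b.area)


class TestRle:
    def test_uncompressed_roundtrip(self):
        rng = np.random.default_rng(1)
        mask = rng.random((13, 7)) > 0.6
        assert np.array_equal(rle_decode(rle_encode(mask)), mask)

    def test_compressed_roundtrip(self):
        rng = np.random.default_rng(2)
        mask = rng.random((23, 31)) > 0.5
        rle = rle_encode(mask, compress=True)
        assert isinstance(rle["counts"], str)
        assert np.array_equal(rle_decode(rle), mask)

    def test_hand_built_column_major_runs(self):
        # 2x2 mask with only the top-right pixel set: column-major runs
        # are [2 background, 1 foreground, 1 background]
        mask = rle_decode({"size": [2, 2], "counts": [2, 1, 1]})
        assert mask.tolist() == [[False, True], [False, False]]

    def test_wrong_total_rejected(self):
        with pytest.raises(ValueError):
            rle_decode({"size": [2, 2], "counts": [3]})


class TestLoadPredictions:
    def write(self, tmp_path, records):
        p = tmp_path / "pred.json"
        p.write_text(json.dumps(records))
        return p

    def records(self):
        square = [10, 10, 30, 10, 30, 30, 10, 30]
        mask = np.zeros((50, 50), bool)
        mask[5:15, 20:40] = True
        return [
            {"image_id": 1, "category_id": 1, "score": 0.9,
             "segmentation": [square]},
            {"image_id": 1, "category_id": 1, "score": 0.4,
             "segmentation": rle_encode(mask)},
        ]

    def test_threshold_above_everything(self, tmp_path):
        p = self.write(tmp_path, self.records())
        assert load_predictions(p, 1.1, {1: (50, 50)}) == {}

    def test_threshold_zero_keeps_all(self, tmp_path):
        p = self.write(tmp_path, self.records())
        preds = load_predictions(p, 0.0, {1: (50, 50)})
        assert len(preds[1]) == 2

    def test_polygon_square_pixel_count(self, tmp_path):
        p = self.write(tmp_path, self.records())
        preds = load_predictions(p, 0.5, {1: (50, 50)})
        (mask, score) = preds[1][0]
        assert score == 0.9
        # interior area 400; boundary convention may add up to a one-pixel ring
        assert 20 * 20 <= mask.sum() <= 21 * 21

    def test_unknown_encoding_rejected(self, tmp_path):
        p = self.write(tmp_path, [{"image_id": 1, "score": 1.0,
                                   "segmentation": "??"}])
        with pytest.raises(ValueError, match="encoding"):
            load_predictions(p)


class TestAugmentation:
    def scene(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 255, (40, 60, 3), dtype=np.uint8)
        inst = make_instance([(5, 5), (20, 8), (18, 25), (6, 22)], h=40, w=60)
        return img, [inst]

    def test_hflip_is_involution(self):
        img, insts = self.scene()
        spec = AugmentationSpec("hflip")
        once = apply_augmentation(img, insts, spec)
        twice = apply_augmentation(*once, spec)
        assert np.array_equal(twice[0], img)
        assert np.allclose(twice[1][0].polygon, insts[0].polygon)

    def test_vflip_is_involution(self):
        img, insts = self.scene()
        spec = AugmentationSpec("vflip")
        img2, insts2 = apply_augmentation(*apply_augmentation(img, insts, spec), spec)
        assert np.array_equal(img2, img)
        assert np.allclose(insts2[0].polygon, insts[0].polygon)

    def test_rotate90_four_times_is_identity(self):
        img, insts = self.scene()
        spec = AugmentationSpec("rotate", {"angle": 90})
        state = (img, insts)
        for _ in range(4):
            state = apply_augmentation(*state, spec)
        assert np.array_equal(state[0], img)
        assert np.allclose(state[1][0].polygon, insts[0].polygon)

    def test_scale_multiplies_polygon_area_exactly(self):
        img, insts = self.scene()
        for s in (0.5, 2.0, 3.0):
            _, out = apply_augmentation(img, insts, AugmentationSpec("scale", {"factor": s}))
            assert out[0].area == pytest.approx(insts[0].area * s * s, rel=1e-12)

    def test_arbitrary_rotation_commutes_with_rasterization(self):
        img = np.zeros((60, 80, 3), np.uint8)
        inst = make_instance([(20, 15), (55, 18), (50, 45), (22, 40)], h=60, w=80)
        img[polygon_to_mask(inst.polygon, 60, 80)] = 255
        spec = AugmentationSpec("rotate", {"angle": 30})
        out_img, (out_inst,) = apply_augmentation(img, [inst], spec)
        mask_from_img = out_img[..., 0] > 127
        mask_from_poly = polygon_to_mask(
            out_inst.polygon, out_img.shape[0], out_img.shape[1]
        )
        inter = (mask_from_img & mask_from_poly).sum()
        union = (mask_from_img | mask_from_poly).sum()
        assert inter / union >= 0.95

    def test_crop_drops_instance_below_visibility(self):
        img, insts = self.scene()
        # crop window far away from the polygon
        _, out = apply_augmentation(
            img, insts, AugmentationSpec("crop", {"x": 40, "y": 30, "width": 20, "height": 10})
        )
        assert out == []

    def test_crop_keeps_contained_instance(self):
        img, insts = self.scene()
        _, out = apply_augmentation(
            img, insts, AugmentationSpec("crop", {"x": 0, "y": 0, "width": 30, "height": 30})
        )
        assert len(out) == 1
        assert out[0].area == pytest.approx(insts[0].area, rel=0.01)

    @pytest.mark.parametrize("op", ["noise", "blur", "cutout", "color_jitter"])
    def test_photometric_ops_leave_polygons_and_are_seeded(self, op):
        img, insts = self.scene()
        spec = AugmentationSpec(op, seed=11)
        out1, insts1 = apply_augmentation(img, insts, spec)
        out2, _ = apply_augmentation(img, insts, spec)
        assert np.array_equal(out1, out2)  # bit-for-bit reproducible
        assert np.allclose(insts1[0].polygon, insts[0].polygon)
        out3, _ = apply_augmentation(img, insts, AugmentationSpec(op, seed=12))
        if op != "blur":  # blur is deterministic regardless of seed
            assert not np.array_equal(out1, out3)

    def test_mosaic_offsets_equal_tile_origins(self):
        imgs, lists = [], []
        for k in range(4):
            img, insts = self.scene()
            imgs.append(img)
            lists.append(insts)
        out, out_insts = apply_augmentation(imgs, lists, AugmentationSpec("mosaic"))
        assert out.shape == (80, 120, 3)
        origins = [(0, 0), (0, 60), (40, 0), (40, 60)]
        for inst, (oy, ox) in zip(out_insts, origins):
            assert np.allclose(inst.polygon, lists[0][0].polygon + [ox, oy])

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec("solarize")


class TestSplitDataset:
    def make_doc(self, n=10):
        instances = [
            make_instance([(0, 0), (5, 0), (0, 5)], image=f"img{i:02d}.png")
            for i in range(n)
        ]
        return to_coco(instances)

    def test_nine_to_one(self):
        train, val = split_dataset(self.make_doc(10), 0.9, seed=0)
        assert len(train["images"]) == 9
        assert len(val["images"]) == 1

    def test_disjoint_and_complete(self):
        doc = self.make_doc(7)
        train, val = split_dataset(doc, 0.7, seed=1)
        t = {im["id"] for im in train["images"]}
        v = {im["id"] for im in val["images"]}
        assert not t & v
        assert t | v == {im["id"] for im in doc["images"]}
        # annotations follow their image
        assert all(a["image_id"] in t for a in train["annotations"])

    def test_deterministic(self):
        doc = self.make_doc(10)
        assert split_dataset(doc, 0.9, 5) == split_dataset(doc, 0.9, 5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            split_dataset(self.make_doc(10), 1.5)
        with pytest.raises(ValueError):
            split_dataset(self.make_doc(1), 0.5)
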