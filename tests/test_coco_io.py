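import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingmark.coco_io import (
    AnnotationValidationError,
    CocoParseError,
    DatasetIndex,
    DegenerateReferenceError,
    LandmarkSet,
    WingAnnotation,
    bbox_from_keypoints,
    convert_measurement_origin,
    load_dataset,
    reference_distance,
    save_dataset,
)
from conftest import make_synthetic_index


def _coco_doc(keypoints, num_keypoints=36, width=4288, height=2848, bbox=None):
    return {
        "images": [{"id": 1, "file_name": "wing.tif", "width": width, "height": height}],
        "annotations": [
            {
                "id": 0,
                "image_id": 1,
                "keypoints": keypoints,
                "num_keypoints": num_keypoints,
                **({"bbox": bbox} if bbox is not None else {}),
            }
        ],
    }


def _valid_keypoints(k=36, width=4288, height=2848, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(100, min(width, height) - 100, size=(k, 2))
    return np.concatenate([pts, np.full((k, 1), 2.0)], axis=1).ravel().tolist()


class TestLoadDataset:
    def test_single_record_with_36_landmarks(self, tmp_path):
        doc = _coco_doc(_valid_keypoints())
        p = tmp_path / "ann.json"
        p.write_text(json.dumps(doc))
        index = load_dataset(p)
        assert len(index) == 1
        assert index.landmark_count == 36
        assert len(index.annotations[0].keypoints) == 108

    def test_empty_dataset_warns_and_k_undefined(self, tmp_path):
        p = tmp_path / "empty.json"
        p.write_text(json.dumps({"images": [], "annotations": []}))
        with pytest.warns(UserWarning, match="no annotations"):
            index = load_dataset(p)
        assert len(index) == 0
        assert index.landmark_count is None

    def test_wrong_keypoint_length_names_record(self, tmp_path):
        kp = _valid_keypoints()[:-1]  # 107 values for num_keypoints=36
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(_coco_doc(kp)))
        with pytest.raises(AnnotationValidationError, match="id=1"):
            load_dataset(p)

    def test_duplicate_image_id_rejected(self, tmp_path):
        doc = _coco_doc(_valid_keypoints())
        doc["images"].append(dict(doc["images"][0]))
        p = tmp_path / "dup.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(CocoParseError, match="duplicate"):
            load_dataset(p)

    def test_coordinates_outside_image_rejected(self, tmp_path):
        kp = _valid_keypoints()
        kp[0] = 99999.0
        p = tmp_path / "oob.json"
        p.write_text(json.dumps(_coco_doc(kp)))
        with pytest.raises(AnnotationValidationError, match="outside"):
            load_dataset(p)

    def test_missing_bbox_gets_tight_padded_box(self, tmp_path):
        kp = _valid_keypoints()
        p = tmp_path / "nobox.json"
        p.write_text(json.dumps(_coco_doc(kp)))
        ann = load_dataset(p).annotations[0]
        pts = ann.points
        x0, y0, w, h = ann.bbox
        assert x0 <= pts[:, 0].min() and x0 + w >= pts[:, 0].max()
        assert y0 <= pts[:, 1].min() and y0 + h >= pts[:, 1].max()
        # padded strictly beyond the tight box (5% each side, interior points)
        assert x0 < pts[:, 0].min() and y0 < pts[:, 1].min()


class TestSaveRoundtrip:
    def test_roundtrip_many_records_field_by_field(self, tmp_path):
        index = make_synthetic_index(256)
        p = tmp_path / "out.json"
        save_dataset(index, p)
        back = load_dataset(p)
        assert back.ids() == index.ids()
        assert back.landmark_count == index.landmark_count
        for a, b in zip(index, back):
            assert a.file_name == b.file_name
            assert (a.width, a.height) == (b.width, b.height)
            np.testing.assert_array_equal(a.keypoints, b.keypoints)
            assert a.bbox == pytest.approx(b.bbox)

    def test_saving_invalid_index_refused(self, tmp_path):
        index = make_synthetic_index(1)
        index.annotations[0].keypoints = index.annotations[0].keypoints[:-3]
        with pytest.raises(AnnotationValidationError):
            save_dataset(index, tmp_path / "bad.json")


class TestMeasurementOrigin:
    @pytest.mark.parametrize(
        "x,y,h,expected",
        [(10.0, 0.0, 2848, (10.0, 2848.0)), (5.0, 2848.0, 2848, (5.0, 0.0))],
    )
    def test_boundaries(self, x, y, h, expected):
        assert convert_measurement_origin(x, y, h) == expected

    @settings(derandomize=True, max_examples=100)
    @given(
        x=st.floats(0, 5000, allow_nan=False),
        y=st.floats(0, 2848, allow_nan=False),
    )
    def test_involution(self, x, y):
        h = 2848
        x1, y1 = convert_measurement_origin(x, y, h)
        x2, y2 = convert_measurement_origin(x1, y1, h)
        assert x2 == x
        assert y2 == pytest.approx(y, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            convert_measurement_origin(1.0, -0.5, 100)
        with pytest.raises(ValueError):
            convert_measurement_origin(1.0, 100.5, 100)


class TestReferenceDistance:
    def test_three_four_five_triangle(self):
        lm = LandmarkSet(points=[(0, 0), (3, 4)], reference_pair=(1, 2))
        assert reference_distance(lm) == pytest.approx(5.0)

    def test_coincident_reference_points_error(self):
        lm = LandmarkSet(points=[(7, 7), (7, 7)], reference_pair=(1, 2))
        with pytest.raises(DegenerateReferenceError):
            reference_distance(lm)

    def test_matches_hypot_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = rng.uniform(0, 4000, size=(36, 2))
            lm = LandmarkSet(points=pts)
            expected = math.hypot(pts[0, 0] - pts[17, 0], pts[0, 1] - pts[17, 1])
            assert abs(reference_distance(lm) - expected) <= 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(36, 2))
        d0 = reference_distance(LandmarkSet(points=pts))
        for _ in range(20):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            moved = pts @ rot.T + rng.uniform(-500, 500, size=2)
            assert reference_distance(LandmarkSet(points=moved)) == pytest.approx(
                d0, abs=1e-9
            )


class TestInvariantsOnRecords:
    def test_keypoint_length_invariant_on_all_fixtures(self, index_256):
        for ann in index_256:
            assert len(ann.keypoints) == 3 * ann.num_keypoints

    def test_visibility_preserved_but_ignored(self, tmp_path):
        kp = _valid_keypoints()
        kp[2] = 0.0  # v flag of landmark 1
        p = tmp_path / "v.json"
        p.write_text(json.dumps(_coco_doc(kp)))
        index = load_dataset(p)
        out = tmp_path / "v2.json"
        save_dataset(index, out)
        assert load_dataset(out).annotations[0].visibility[0] == 0.0

    def test_landmark_set_requires_valid_reference_pair(self):
        with pytest.raises(ValueError):
            LandmarkSet(points=[(0, 0), (1, 1)], reference_pair=(1, 1))
        with pytest.raises(ValueError):
            LandmarkSet(points=[(0, 0), (1, 1)], reference_pair=(1, 18))

    def test_bbox_from_keypoints_clips_to_image(self):
        pts = np.array([[1.0, 1.0], [99.0, 99.0]])
        x0, y0, w, h = bbox_from_keypoints(pts, 100, 100, pad_fraction=0.5)
        assert x0 >= 0 and y0 >= 0 and x0 + w <= 100 and y0 + h <= 100
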