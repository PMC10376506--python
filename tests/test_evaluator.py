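"""NME metric correctness, report aggregation and overlay rendering."""

import math

import numpy as np
import pytest
from PIL import Image

from wingmark.coco_io import LandmarkSet, landmarks_from_annotation, reference_distance
from wingmark.codec import CodecConfig, encode
from wingmark.evaluator import (
    NMEReport,
    aggregate_groups,
    evaluate_model,
    nme,
    normalized_errors,
    render_overlay,
)


def _lm(points):
    return LandmarkSet(points=points, reference_pair=(1, 2))


class TestNME:
    def test_perfect_prediction_is_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(36, 2))
        assert nme(LandmarkSet(points=pts), LandmarkSet(points=pts.copy()), d=50.0) == 0.0

    def test_uniform_offset_of_d_gives_one(self):
        truth = _lm([(0.0, 0.0), (10.0, 0.0)])
        pred = _lm([(0.0, 7.5), (10.0, 7.5)])  # both off by exactly d=7.5
        assert nme(pred, truth, d=7.5) == pytest.approx(1.0)

    def test_matches_brute_force_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.uniform(0, 4000, size=(36, 2))
            p = t + rng.normal(0, 20, size=(36, 2))
            d = float(rng.uniform(100, 2000))
            acc = 0.0
            for i in range(36):
                acc += math.hypot(p[i, 0] - t[i, 0], p[i, 1] - t[i, 1]) / d
            expected = acc / 36
            got = nme(LandmarkSet(points=p), LandmarkSet(points=t), d)
            assert abs(got - expected) <= 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 100, size=(36, 2))
        p = t + rng.normal(0, 3, size=(36, 2))
        base = nme(LandmarkSet(points=p), LandmarkSet(points=t), d=40.0)
        for s in (0.1, 3.0, 250.0):
            scaled = nme(
                LandmarkSet(points=p * s), LandmarkSet(points=t * s), d=40.0 * s
            )
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 100, size=(36, 2))
        p = t + rng.normal(0, 3, size=(36, 2))
        base = nme(LandmarkSet(points=p), LandmarkSet(points=t), d=40.0)
        shift = np.array([123.4, -56.7])
        assert nme(
            LandmarkSet(points=p + shift), LandmarkSet(points=t + shift), d=40.0
        ) == pytest.approx(base, rel=1e-12)

    def test_invalid_inputs(self):
        a = _lm([(0, 0), (1, 1)])
        b = LandmarkSet(points=np.zeros((3, 2)), reference_pair=(1, 2))
        with pytest.raises(ValueError):
            nme(a, a, d=0.0)
        with pytest.raises(ValueError):
            nme(a, b, d=1.0)


class _StubModel:
    """Returns pre-computed heatmap stacks in test-sample order."""

    def __init__(self, config, outputs):
        self.config = config
        self._outputs = list(outputs)
        self._i = 0

    def predict(self, x):
        out = self._outputs[self._i]
        self._i += 1
        return out[None]


class TestEvaluateModel:
    @pytest.fixture()
    def target_samples(self, small_source_dataset):
        return small_source_dataset.samples(ids=[0, 1, 2, 3])

    def _oracle_outputs(self, samples, codec, offset=0.0):
        outs = []
        for _img, ann in samples:
            lm = landmarks_from_annotation(ann)
            pts = lm.points.copy()
            if offset:
                d = reference_distance(lm)
                pts[:, 0] += offset * d
            shifted = LandmarkSet(points=pts, reference_pair=lm.reference_pair)
            outs.append(encode(shifted, ann.bbox, codec).values)
        return outs

    def test_ground_truth_oracle_scores_zero(self, target_samples):
        from wingmark.hrnet import tiny_config

        cfg = tiny_config(36, (64, 64))
        codec = CodecConfig(input_size=(64, 64), heatmap_size=(16, 16))
        model = _StubModel(cfg, self._oracle_outputs(target_samples, codec))
        report = evaluate_model(model, target_samples, codec)
        assert report.mean_nme == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(report.per_landmark_nme, 0.0, atol=1e-10)

    def test_five_percent_offset_gives_nme_0_05(self, target_samples):
        from wingmark.hrnet import tiny_config

        cfg = tiny_config(36, (64, 64))
        codec = CodecConfig(input_size=(64, 64), heatmap_size=(16, 16))
        model = _StubModel(cfg, self._oracle_outputs(target_samples, codec, offset=0.05))
        report = evaluate_model(model, target_samples, codec)
        assert report.mean_nme == pytest.approx(0.05, abs=1e-3)

    def test_per_landmark_mean_consistency(self, target_samples):
        from wingmark.hrnet import tiny_config

        cfg = tiny_config(36, (64, 64))
        codec = CodecConfig(input_size=(64, 64), heatmap_size=(16, 16))
        model = _StubModel(cfg, self._oracle_outputs(target_samples, codec, offset=0.02))
        report = evaluate_model(model, target_samples, codec)
        assert report.mean_nme == pytest.approx(report.per_sample_nme.mean(), abs=1e-12)
        assert report.mean_nme == pytest.approx(report.per_landmark_nme.mean(), abs=1e-12)


def _report(mean, strategy="TS", size=3, k=36):
    per_lm = np.full(k, mean)
    return NMEReport(
        per_landmark_nme=per_lm,
        mean_nme=mean,
        per_sample_nme=np.full(5, mean),
        reference_distances=np.full(5, 100.0),
        metadata={"strategy": strategy, "group_size": size},
    )


class TestAggregation:
    def test_identical_reports_zero_std(self):
        table = aggregate_groups([_report(0.021)] * 10)
        row = table.iloc[0]
        assert row["mean_nme"] == pytest.approx(0.021)
        assert row["std_nme"] == pytest.approx(0.0)
        assert row["n_groups"] == 10

    def test_two_reports_hand_computed_std(self):
        table = aggregate_groups([_report(0.02), _report(0.04)])
        row = table.iloc[0]
        assert row["mean_nme"] == pytest.approx(0.03)
        # sample std, n-1 denominator: sqrt(((0.02-0.03)^2 + (0.04-0.03)^2)/1)
        assert row["std_nme"] == pytest.approx(math.sqrt(2e-4 / 1), rel=1e-9)

    def test_permutation_invariance(self):
        reports = [_report(v, size=s) for v in (0.01, 0.02, 0.03) for s in (3, 10)]
        a = aggregate_groups(reports)
        b = aggregate_groups(reports[::-1])
        assert a.equals(b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_groups([])


class TestOverlay:
    def test_writes_valid_image_with_both_colors(self, tmp_path):
        canvas = np.zeros((64, 64), dtype=np.uint8)
        truth = _lm([(10, 10), (50, 12), (30, 40)][:2])
        pred = _lm([(12, 30), (52, 45)])
        out = tmp_path / "overlay.png"
        render_overlay(canvas, truth, pred, out, radius=3, label=False)
        arr = np.asarray(Image.open(out).convert("RGB"))
        red = ((arr[:, :, 0] > 200) & (arr[:, :, 1] < 50) & (arr[:, :, 2] < 50)).sum()
        blue = ((arr[:, :, 2] > 200) & (arr[:, :, 0] < 50) & (arr[:, :, 1] < 50)).sum()
        assert red >= 2 * 9  # at least a few pixels per marker of each color
        assert blue >= 2 * 9

    def test_mismatched_sets_rejected_nothing_written(self, tmp_path):
        canvas = np.zeros((32, 32), dtype=np.uint8)
        truth = _lm([(1, 1), (2, 2), (3, 3)])
        pred = _lm([(1, 1), (2, 2)])
        out = tmp_path / "bad.png"
        with pytest.raises(ValueError):
            render_overlay(canvas, truth, pred, out)
        assert not out.exists()
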