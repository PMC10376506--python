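import numpy as np
import pytest

from wingmark.coco_io import LandmarkSet
from wingmark.codec import (
    CodecConfig,
    HeatmapStack,
    crop_window,
    decode,
    encode,
    mse_loss,
)


def _lm(points, **kw):
    kw.setdefault("reference_pair", (1, 2))
    return LandmarkSet(points=points, **kw)


def brute_force_gaussian(u, v, hh, hw, sigma):
    """Dense double-loop oracle: Gaussian at every cell, normalized to peak 1."""
    g = np.zeros((hh, hw))
    for i in range(hh):
        for j in range(hw):
            g[i, j] = np.exp(-((j - u) ** 2 + (i - v) ** 2) / (2 * sigma**2))
    return g / g.max()


SQUARE = CodecConfig(input_size=(256, 256), heatmap_size=(64, 64), sigma=2.0)


class TestEncode:
    def test_peak_at_window_center(self):
        bbox = (0.0, 0.0, 100.0, 100.0)
        window = crop_window(bbox, SQUARE)
        cx = window[0] + window[2] / 2
        cy = window[1] + window[3] / 2
        stack = encode(_lm([(cx, cy), (cx, cy)]), bbox, SQUARE)
        i, j = np.unravel_index(np.argmax(stack.values[0]), (64, 64))
        # grid center falls between cells 31 and 32; row-major ties pick 31
        assert (i, j) in ((31, 31), (31, 32), (32, 31), (32, 32))
        assert stack.values[0].max() == pytest.approx(1.0)

    def test_out_of_crop_landmark_zero_channel_with_warning(self):
        bbox = (100.0, 100.0, 50.0, 50.0)
        with pytest.warns(UserWarning, match="outside the crop"):
            stack = encode(_lm([(125, 125), (5000, 5000)]), bbox, SQUARE)
        assert stack.values[1].max() == 0.0
        assert stack.values[0].max() == pytest.approx(1.0)

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(3)
        bbox = (10.0, 20.0, 200.0, 150.0)
        window = crop_window(bbox, SQUARE)
        x0, y0, ww, wh = window
        pts = np.column_stack(
            [rng.uniform(x0 + 20, x0 + ww - 20, 4), rng.uniform(y0 + 20, y0 + wh - 20, 4)]
        )
        stack = encode(_lm(pts), bbox, SQUARE)
        sx, sy = stack.scale
        for c in range(4):
            u = (pts[c, 0] - x0) / sx - 0.5
            v = (pts[c, 1] - y0) / sy - 0.5
            expected = brute_force_gaussian(u, v, 64, 64, SQUARE.sigma)
            assert np.abs(stack.values[c] - expected).max() <= 1e-6

    def test_nonpositive_bbox_rejected(self):
        with pytest.raises(ValueError):
            encode(_lm([(0, 0), (1, 1)]), (0, 0, 0, 10), SQUARE)

    def test_shift_equivariance_by_whole_cells(self):
        """Translating the landmark by an integer number of heatmap cells
        translates the encoded channel by the same number of cells."""
        bbox = (0.0, 0.0, 256.0, 256.0)
        window = crop_window(bbox, SQUARE)
        sx, sy = window[2] / 64, window[3] / 64
        p = (window[0] + 20 * sx, window[1] + 25 * sy)
        q = (p[0] + 3 * sx, p[1] + 5 * sy)
        a = encode(_lm([p, p]), bbox, SQUARE).values[0]
        b = encode(_lm([q, q]), bbox, SQUARE).values[0]
        np.testing.assert_allclose(a[:-5, :-3], b[5:, 3:], atol=1e-12)


class TestDecode:
    def test_delta_function_decodes_to_cell_center(self):
        vals = np.zeros((2, 64, 64))
        vals[0, 10, 20] = 1.0
        vals[1, 1, 1] = 1.0
        stack = HeatmapStack(vals, input_window=(0, 0, 256, 256), scale=(4.0, 4.0))
        cfg = CodecConfig(refine="none")
        lm = decode(stack, cfg)
        assert tuple(lm.points[0]) == ((20 + 0.5) * 4.0, (10 + 0.5) * 4.0)

    def test_tie_breaks_to_first_in_row_major_order(self):
        vals = np.zeros((2, 64, 64))
        vals[0, 5, 5] = 1.0
        vals[0, 40, 40] = 1.0  # equal maxima
        vals[1, 0, 0] = 1.0
        stack = HeatmapStack(vals, input_window=(0, 0, 256, 256), scale=(4.0, 4.0))
        lm = decode(stack, CodecConfig(refine="none"))
        assert tuple(lm.points[0]) == ((5 + 0.5) * 4.0, (5 + 0.5) * 4.0)

    def test_all_zero_channel_flagged_and_centered(self):
        vals = np.zeros((2, 64, 64))
        vals[0, 3, 3] = 1.0
        stack = HeatmapStack(vals, input_window=(0, 0, 256, 256), scale=(4.0, 4.0))
        lm, flags = decode(stack, CodecConfig(), return_flags=True)
        assert flags.tolist() == [False, True]
        assert tuple(lm.points[1]) == (128.0, 128.0)

    @pytest.mark.parametrize(
        "refine,bound_px",
        [("none", 0.5 * 4.0 * (1 + 0.25)), ("parabola", 0.5)],
    )
    def test_roundtrip_bound(self, refine, bound_px):
        """encode -> decode errs by at most half a cell unrefined, and under
        half an input pixel with sub-cell refinement, for interior landmarks."""
        cfg = CodecConfig(
            input_size=(256, 256), heatmap_size=(64, 64), sigma=2.0, refine=refine
        )
        rng = np.random.default_rng(123)
        bbox = (30.0, 40.0, 180.0, 170.0)
        window = crop_window(bbox, cfg)
        x0, y0, ww, wh = window
        sx, sy = ww / 64, wh / 64
        margin = 2 * cfg.sigma  # cells
        n = 1000
        pts = np.column_stack(
            [
                rng.uniform(x0 + margin * sx, x0 + ww - margin * sx, n),
                rng.uniform(y0 + margin * sy, y0 + wh - margin * sy, n),
            ]
        )
        max_err = 0.0
        for start in range(0, n, 36):
            chunk = pts[start : start + 36]
            if len(chunk) < 2:
                chunk = np.vstack([chunk, chunk])
            stack = encode(LandmarkSet(points=chunk, reference_pair=(1, 2)), bbox, cfg)
            dec = decode(stack, cfg)
            err = np.abs(dec.points - chunk)
            max_err = max(max_err, err.max())
        assert max_err <= bound_px

    def test_quarter_refinement_shifts_toward_larger_neighbor(self):
        vals = np.zeros((2, 64, 64))
        vals[0, 10, 20] = 1.0
        vals[0, 10, 21] = 0.5  # larger right neighbor
        vals[1, 30, 30] = 1.0
        stack = HeatmapStack(vals, input_window=(0, 0, 256, 256), scale=(4.0, 4.0))
        lm = decode(stack, CodecConfig(refine="quarter"))
        assert lm.points[0][0] == pytest.approx((20 + 0.25 + 0.5) * 4.0)

    def test_non_finite_heatmap_rejected(self):
        vals = np.zeros((2, 8, 8))
        stack = HeatmapStack(vals, input_window=(0, 0, 32, 32), scale=(4.0, 4.0))
        stack.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            decode(stack, CodecConfig(input_size=(32, 32), heatmap_size=(8, 8)))


class TestMseLoss:
    def test_identical_stacks_zero(self):
        a = np.random.default_rng(0).normal(size=(4, 8, 8))
        assert mse_loss(a, a.copy()) == 0.0

    def test_constant_offset_squared(self):
        a = np.zeros((3, 8, 8))
        assert mse_loss(a, a + 0.7) == pytest.approx(0.49)

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(5, 16, 16))
        b = rng.normal(size=(5, 16, 16))
        total = 0.0
        for c in range(5):
            for i in range(16):
                for j in range(16):
                    total += (a[c, i, j] - b[c, i, j]) ** 2
        assert abs(mse_loss(a, b) - total / a.size) <= 1e-10

    def test_symmetry_and_triangle_surrogate(self):
        rng = np.random.default_rng(10)
        a, b, c = rng.normal(size=(3, 4, 8, 8))
        assert mse_loss(a, b) == mse_loss(b, a)
        assert mse_loss(a, c) <= 2 * (mse_loss(a, b) + mse_loss(b, c)) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)))


def test_heatmap_archive_roundtrip(tmp_path):
    from wingmark.codec import load_heatmaps, save_heatmaps

    bbox = (0.0, 0.0, 100.0, 100.0)
    stack = encode(_lm([(30, 30), (60, 70)]), bbox, SQUARE)
    path = tmp_path / "maps.npz"
    save_heatmaps(stack, path)
    back = load_heatmaps(path)
    np.testing.assert_array_equal(back.values, stack.values)
    assert back.input_window == pytest.approx(stack.input_window)
    assert back.scale == pytest.approx(stack.scale)


class TestConfig:
    def test_input_must_be_multiple_of_heatmap(self):
        with pytest.raises(ValueError):
            CodecConfig(input_size=(100, 100), heatmap_size=(64, 64))

    def test_sigma_positive(self):
        with pytest.raises(ValueError):
            CodecConfig(sigma=0.0)
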