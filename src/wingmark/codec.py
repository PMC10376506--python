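"""Gaussian heatmap encoding/decoding and the MSE training loss.

A landmark at continuous image position p is represented, per channel, by a
2-D Gaussian on a coarse heatmap grid; the network regresses these maps and
the decoder inverts them back to image coordinates.  The grid covers a crop
window derived from the wing's bounding box (expanded to the network input's
aspect ratio and padded), so heatmap cell (i, j) corresponds to the image
point ``(x0 + (j + 0.5) * sx, y0 + (i + 0.5) * sy)``.

Encoded channels are normalized to peak value 1 at the cell nearest the
landmark.  Decoding takes the per-channel argmax (first in row-major order
on ties) and optionally refines it to sub-cell precision; because the
normalization constant cancels in log-space differences, the default
log-parabola refinement recovers the continuous peak of an ideal Gaussian
channel exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .coco_io import LandmarkSet

__all__ = [
    "CodecConfig",
    "HeatmapStack",
    "crop_window",
    "extract_input",
    "encode",
    "decode",
    "mse_loss",
    "save_heatmaps",
    "load_heatmaps",
]


@dataclass
class CodecConfig:
    """Geometry and shape of the heatmap representation.

    input_size / heatmap_size are (height, width); input dims must be integer
    multiples of the heatmap dims (the backbone's stride).  ``sigma`` is the
    Gaussian std in heatmap cells.  ``refine`` selects sub-cell decoding:
    "parabola" (log-parabola peak fit), "quarter" (0.25-cell shift toward the
    larger neighbor) or "none".
    """

    input_size: tuple[int, int] = (256, 256)
    heatmap_size: tuple[int, int] = (64, 64)
    sigma: float = 2.0
    refine: str = "parabola"
    pad_fraction: float = 0.25

    def __post_init__(self):
        ih, iw = self.input_size
        hh, hw = self.heatmap_size
        if ih % hh or iw % hw:
            raise ValueError(
                f"input_size {self.input_size} must be integer multiples of "
                f"heatmap_size {self.heatmap_size}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.refine not in ("parabola", "quarter", "none"):
            raise ValueError(f"unknown refinement mode {self.refine!r}")


@dataclass
class HeatmapStack:
    """Per-landmark score maps plus the geometry linking them to the image."""

    values: np.ndarray  # (C, H, W)
    input_window: tuple[float, float, float, float]  # (x0, y0, w, h) image px
    scale: tuple[float, float]  # input-pixels-per-heatmap-cell (sx, sy)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("heatmap values must have shape (C, H, W)")
        if not np.isfinite(self.values).all():
            raise ValueError("heatmap values must be finite")

    @property
    def num_channels(self) -> int:
        return self.values.shape[0]


def crop_window(
    bbox: tuple[float, float, float, float],
    config: CodecConfig,
) -> tuple[float, float, float, float]:
    """Expand a bbox to the input aspect ratio and pad it.

    The window is centered on the bbox center; it may extend past the image
    border (extraction replicates edge pixels there).
    """
    x0, y0, bw, bh = bbox
    if bw <= 0 or bh <= 0:
        raise ValueError(f"bbox has non-positive size: {bbox}")
    cx, cy = x0 + bw / 2.0, y0 + bh / 2.0
    ih, iw = config.input_size
    aspect = iw / ih
    if bw / bh < aspect:
        bw = bh * aspect
    else:
        bh = bw / aspect
    bw *= 1.0 + config.pad_fraction
    bh *= 1.0 + config.pad_fraction
    return (cx - bw / 2.0, cy - bh / 2.0, bw, bh)


def extract_input(image: np.ndarray, window, config: CodecConfig) -> np.ndarray:
    """Crop ``window`` from an image array and resize to the network input.

    Returns a float32 array of shape (channels, H_in, W_in) scaled to [0, 1].
    Regions of the window outside the image replicate the nearest edge pixel.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w, _ = arr.shape
    x0, y0, ww, wh = window
    pad_l = max(0, int(np.ceil(-x0)))
    pad_t = max(0, int(np.ceil(-y0)))
    pad_r = max(0, int(np.ceil(x0 + ww - w)))
    pad_b = max(0, int(np.ceil(y0 + wh - h)))
    if pad_l or pad_t or pad_r or pad_b:
        arr = np.pad(arr, ((pad_t, pad_b), (pad_l, pad_r), (0, 0)), mode="edge")
        x0 += pad_l
        y0 += pad_t
    ih, iw = config.input_size
    channels = []
    for c in range(arr.shape[2]):
        im = Image.fromarray(arr[:, :, c].astype(np.float32), mode="F")
        im = im.resize((iw, ih), resample=Image.BILINEAR, box=(x0, y0, x0 + ww, y0 + wh))
        channels.append(np.asarray(im, dtype=np.float32))
    out = np.stack(channels, axis=0)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out /= 255.0
    return out


def _grid_coords(points: np.ndarray, window, config: CodecConfig):
    """Map image-pixel points to continuous heatmap cell coordinates (u, v)."""
    x0, y0, ww, wh = window
    hh, hw = config.heatmap_size
    sx, sy = ww / hw, wh / hh
    u = (points[:, 0] - x0) / sx - 0.5
    v = (points[:, 1] - y0) / sy - 0.5
    return u, v, sx, sy


def encode(
    landmarks: LandmarkSet,
    bbox: tuple[float, float, float, float],
    config: CodecConfig,
) -> HeatmapStack:
    """Encode landmark coordinates as peak-normalized Gaussian heatmaps.

    Landmarks falling outside the padded crop window get an all-zero channel
    and a warning; everything else yields a channel whose maximum is exactly
    1 at the grid cell nearest the landmark.
    """
    window = crop_window(bbox, config)
    hh, hw = config.heatmap_size
    u, v, sx, sy = _grid_coords(landmarks.points, window, config)
    jj = np.arange(hw, dtype=float)
    ii = np.arange(hh, dtype=float)
    two_s2 = 2.0 * config.sigma**2
    maps = np.zeros((len(landmarks), hh, hw), dtype=float)
    for c in range(len(landmarks)):
        if not (-0.5 <= u[c] <= hw - 0.5 and -0.5 <= v[c] <= hh - 0.5):
            warnings.warn(
                f"landmark {c + 1} lies outside the crop window; zero channel",
                stacklevel=2,
            )
            continue
        g = np.exp(
            -(((jj[None, :] - u[c]) ** 2) + ((ii[:, None] - v[c]) ** 2)) / two_s2
        )
        maps[c] = g / g.max()
    return HeatmapStack(values=maps, input_window=window, scale=(sx, sy))


def _refine_1d(vals: np.ndarray, idx: int, mode: str) -> float:
    """Sub-cell offset along one axis given the argmax index."""
    n = len(vals)
    if mode == "none" or idx == 0 or idx == n - 1:
        return 0.0
    lo, mid, hi = vals[idx - 1], vals[idx], vals[idx + 1]
    if mode == "quarter":
        if hi > lo:
            return 0.25
        if lo > hi:
            return -0.25
        return 0.0
    # log-parabola: exact for a sampled Gaussian with positive neighbors
    if lo <= 0 or hi <= 0 or mid <= 0:
        return _refine_1d(vals, idx, "quarter")
    llo, lmid, lhi = np.log(lo), np.log(mid), np.log(hi)
    denom = llo - 2.0 * lmid + lhi
    if denom >= 0:
        return _refine_1d(vals, idx, "quarter")
    delta = 0.5 * (llo - lhi) / denom
    return float(np.clip(delta, -0.5, 0.5))


def decode(
    stack: HeatmapStack,
    config: CodecConfig,
    return_flags: bool = False,
):
    """Decode a heatmap stack back to image-space landmark coordinates.

    Per channel: argmax (first in row-major order on ties), optional sub-cell
    refinement, then the cell-center mapping back to image pixels.  All-zero
    channels are undecodable: they contribute the crop center and, with
    ``return_flags=True``, a True entry in the returned boolean mask.
    """
    vals = stack.values
    if not np.isfinite(vals).all():
        raise ValueError("cannot decode non-finite heatmaps")
    c, hh, hw = vals.shape
    x0, y0, ww, wh = stack.input_window
    sx, sy = stack.scale
    points = np.empty((c, 2), dtype=float)
    flags = np.zeros(c, dtype=bool)
    for k in range(c):
        chan = vals[k]
        if chan.max() <= 0:
            points[k] = (x0 + ww / 2.0, y0 + wh / 2.0)
            flags[k] = True
            continue
        flat = int(np.argmax(chan))
        i, j = divmod(flat, hw)
        u = j + _refine_1d(chan[i, :], j, config.refine)
        v = i + _refine_1d(chan[:, j], i, config.refine)
        points[k] = (x0 + (u + 0.5) * sx, y0 + (v + 0.5) * sy)
    k_pts = max(c, 2)
    if c < 2:  # LandmarkSet requires K >= 2; degenerate stacks are padded
        points = np.vstack([points, [[x0, y0]]])
    ref = (1, 2) if k_pts < 18 else (1, 18)
    out = LandmarkSet(points=points, reference_pair=ref)
    if return_flags:
        return out, flags
    return out


def save_heatmaps(stack: HeatmapStack, path) -> None:
    """Archive a heatmap stack (values + crop geometry) as NPZ for debugging."""
    np.savez(
        path,
        values=stack.values,
        input_window=np.asarray(stack.input_window, dtype=float),
        scale=np.asarray(stack.scale, dtype=float),
    )


def load_heatmaps(path) -> HeatmapStack:
    with np.load(path) as npz:
        return HeatmapStack(
            values=npz["values"],
            input_window=tuple(npz["input_window"]),
            scale=tuple(npz["scale"]),
        )


def mse_loss(predicted, target) -> float:
    """Mean squared error over all elements of two equal-shape heatmap stacks."""
    a = predicted.values if isinstance(predicted, HeatmapStack) else np.asarray(predicted)
    b = target.values if isinstance(target, HeatmapStack) else np.asarray(target)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a.astype(float) - b.astype(float)
    return float(np.mean(diff * diff))
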