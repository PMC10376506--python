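"""Normalized mean error (NME) evaluation and result aggregation.

For one specimen with K landmarks, truth P and prediction P-hat,

    NME = (1 / K) * sum_i ||p_i - p_hat_i|| / d,

where d is the specimen's reference distance — here the distance between
landmark 1 (proximal anterior point of the humeral plate) and landmark 18
(distal point of RA1), computed from the ground-truth positions so that
predictions cannot contaminate the normalizer.  Per-landmark profiles
average each landmark's normalized error over test specimens; group
summaries report mean +/- sample standard deviation (n-1 denominator) of
the per-model mean NME across replicate training groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .coco_io import (
    DegenerateReferenceError,
    LandmarkSet,
    WingAnnotation,
    landmarks_from_annotation,
    reference_distance,
)
from .codec import CodecConfig, HeatmapStack, crop_window, decode, extract_input
from .hrnet import HRNet

__all__ = [
    "NMEReport",
    "nme",
    "normalized_errors",
    "evaluate_model",
    "aggregate_groups",
    "render_overlay",
]


def normalized_errors(predicted: LandmarkSet, truth: LandmarkSet, d: float) -> np.ndarray:
    """Per-landmark normalized Euclidean errors ||p_i - p_hat_i|| / d."""
    if d <= 0:
        raise ValueError(f"reference distance must be positive, got {d}")
    p = np.asarray(predicted.points, dtype=float)
    t = np.asarray(truth.points, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"landmark count mismatch: {p.shape[0]} vs {t.shape[0]}")
    return np.linalg.norm(p - t, axis=1) / d


def nme(predicted: LandmarkSet, truth: LandmarkSet, d: float) -> float:
    """Mean normalized error over the K landmarks of one specimen."""
    return float(normalized_errors(predicted, truth, d).mean())


@dataclass
class NMEReport:
    """Evaluation of one model on one test set."""

    per_landmark_nme: np.ndarray  # (K,)
    mean_nme: float
    per_sample_nme: np.ndarray  # (N,)
    reference_distances: np.ndarray  # (N,)
    metadata: dict = field(default_factory=dict)
    excluded_samples: int = 0

    def __post_init__(self):
        self.per_landmark_nme = np.asarray(self.per_landmark_nme, dtype=float)
        self.per_sample_nme = np.asarray(self.per_sample_nme, dtype=float)
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)

    def to_dict(self) -> dict:
        return {
            "mean_nme": self.mean_nme,
            "per_landmark_nme": self.per_landmark_nme.tolist(),
            "per_sample_nme": self.per_sample_nme.tolist(),
            "reference_distances": self.reference_distances.tolist(),
            "excluded_samples": self.excluded_samples,
            "metadata": dict(self.metadata),
        }


def evaluate_model(
    model: HRNet,
    test_samples: list[tuple[np.ndarray, WingAnnotation]],
    codec: CodecConfig | None = None,
    metadata: dict | None = None,
) -> NMEReport:
    """Run the model over a test set and compute the NME report.

    Each sample's d comes from its own ground-truth reference pair; samples
    with a degenerate (zero) reference distance are excluded and counted.
    Undecodable heatmap channels contribute the crop-center fallback
    position rather than being dropped.
    """
    if codec is None:
        codec = CodecConfig(
            input_size=model.config.input_size,
            heatmap_size=model.config.heatmap_size(),
        )
    errors = []  # (N, K)
    dists = []
    excluded = 0
    for image, ann in test_samples:
        truth = landmarks_from_annotation(ann)
        try:
            d = reference_distance(truth)
        except DegenerateReferenceError:
            excluded += 1
            continue
        window = crop_window(ann.bbox, codec)
        x = extract_input(image, window, codec)
        if x.shape[0] == 1 and model.config.in_channels == 3:
            x = np.repeat(x, 3, axis=0)
        elif x.shape[0] == 3 and model.config.in_channels == 1:
            x = x.mean(axis=0, keepdims=True)
        out = model.predict(x[None])[0]
        hh, hw = codec.heatmap_size
        stack = HeatmapStack(
            values=out,
            input_window=window,
            scale=(window[2] / hw, window[3] / hh),
        )
        predicted = decode(stack, codec)
        errors.append(normalized_errors(predicted, truth, d))
        dists.append(d)
    if not errors:
        raise ValueError("no evaluable test samples (all degenerate or empty)")
    err = np.asarray(errors)
    per_sample = err.mean(axis=1)
    return NMEReport(
        per_landmark_nme=err.mean(axis=0),
        mean_nme=float(per_sample.mean()),
        per_sample_nme=per_sample,
        reference_distances=np.asarray(dists),
        metadata=metadata or {},
        excluded_samples=excluded,
    )


def aggregate_groups(reports: list[NMEReport]) -> pd.DataFrame:
    """Summarize replicate-group reports per (strategy, training-set size).

    Returns a table with mean and sample standard deviation (ddof=1) of the
    group-level mean NME, the replicate count, and per-landmark mean NMEs;
    invariant under report ordering.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    k_counts = {len(r.per_landmark_nme) for r in reports}
    if len(k_counts) != 1:
        raise ValueError(f"reports disagree on landmark count: {sorted(k_counts)}")
    rows = []
    for r in reports:
        rows.append(
            {
                "strategy": r.metadata.get("strategy", ""),
                "group_size": r.metadata.get("group_size", len(r.per_sample_nme)),
                "mean_nme": r.mean_nme,
                "per_landmark": r.per_landmark_nme,
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for (strategy, size), grp in frame.groupby(["strategy", "group_size"], sort=True):
        values = grp["mean_nme"].to_numpy()
        per_lm = np.mean(np.stack(grp["per_landmark"].to_list()), axis=0)
        row = {
            "strategy": strategy,
            "group_size": size,
            "n_groups": len(values),
            "mean_nme": float(values.mean()),
            "std_nme": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        }
        for i, v in enumerate(per_lm):
            row[f"landmark_{i + 1}_nme"] = float(v)
        out.append(row)
    return pd.DataFrame(out)


def render_overlay(
    image: np.ndarray,
    truth: LandmarkSet,
    predicted: LandmarkSet,
    out_path,
    radius: int = 4,
    label: bool = True,
) -> None:
    """Write an overlay image: truth in red, predictions in blue, indices labeled."""
    if len(truth) == 0 or len(predicted) == 0:
        raise ValueError("cannot render an empty landmark set")
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction must have the same landmark count")
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    img = Image.fromarray(arr).convert("RGB")
    draw = ImageDraw.Draw(img)
    for idx, (tp, pp) in enumerate(zip(truth.points, predicted.points), start=1):
        for (x, y), color in ((tp, (255, 0, 0)), (pp, (0, 0, 255))):
            draw.ellipse(
                (x - radius, y - radius, x + radius, y + radius),
                outline=color,
                fill=color,
            )
        if label:
            draw.text((tp[0] + radius + 1, tp[1] - radius - 1), str(idx), fill=(255, 0, 0))
    img.save(out_path)
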