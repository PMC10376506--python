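"""Reading, validating and writing hindwing landmark datasets.

The annotation dialect is a narrow slice of the COCO keypoint format: one
wing per image, a flat ``keypoints`` array of length ``3 * num_keypoints``
holding (x, y, v) triplets in pixels with a top-left origin, and a ``bbox``
of (x_min, y_min, width, height).  The visibility flag ``v`` is preserved on
round-trips but ignored by all computation — every landmark on a dissected,
flattened wing is visible.

Measurement software often reports coordinates with a lower-left origin;
:func:`convert_measurement_origin` maps those to the stored convention by
subtracting the measured y from the image height.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CocoParseError",
    "AnnotationValidationError",
    "DegenerateReferenceError",
    "WingAnnotation",
    "LandmarkSet",
    "DatasetIndex",
    "HINDWING_LANDMARK_NAMES",
    "load_dataset",
    "save_dataset",
    "convert_measurement_origin",
    "reference_distance",
    "bbox_from_keypoints",
]


class CocoParseError(ValueError):
    """The JSON is structurally not a wing keypoint dataset."""


class AnnotationValidationError(ValueError):
    """A record violates a dataset invariant; the message names the record."""


class DegenerateReferenceError(ValueError):
    """The two reference landmarks coincide, so normalized error is undefined."""


#: Vein-anatomy descriptions of the 36 hindwing landmarks, in storage order
#: (index 0 is landmark 1).  Abbreviations follow standard venation
#: nomenclature: Sc subcosta, RA/RP radius anterior/posterior, MP media
#: posterior, CuA cubitus anterior, AA/AP anal veins, cv cross-vein.
HINDWING_LANDMARK_NAMES: tuple[str, ...] = (
    "Proximal anterior point of humeral plate (HP)",
    "Crossing point of BSc and Sc",
    "Point where Sc bifurcates into ScA and ScP",
    "Crossing point of ScP and RA",
    "Crossing point of ScA and RA",
    "Crossing point of rp-m1 and RA",
    "Proximal anterior point of radial cell",
    "Distal anterior point of radial cell",
    "Distal posterior point of radial cell",
    "Anterior point of r4 at the radial cell",
    "Proximal posterior point of radial cell",
    "Proximal point of r3",
    "Apical hinge",
    "Anterior point of the triangular area distal to the radial cell",
    "Posterior point of the triangular area distal to the radial cell",
    "Proximal point of the triangular area distal to the radial cell",
    "Distal point of RA4",
    "Distal point of RA1",
    "Distal point of RP2",
    "Bifurcation point of MP1+2",
    "Posterior point of r4 at rp-mp2",
    "Proximal point of RP",
    "Anterior point of mp-cua",
    "Crossing point of rm-mp1 and MP",
    "Posterior point of the medial spur",
    "Posterior point of mp-cua",
    "Bifurcation point of AA",
    "Fusion point of AA1+2 with CuA3+4",
    "Distal point of AA3+4",
    "Proximal point of cv",
    "Distal point of AA1+2+CuA3+4",
    "Anterior point of CuA1+2+MP4",
    "Distal point of cv",
    "Posterior point of CuA1+2+MP4",
    "Base point of AP3+4",
    "Posterior point of AP3+4",
)


@dataclass
class WingAnnotation:
    """One image's record: identity, geometry and the keypoint array."""

    image_id: int
    file_name: str
    width: int
    height: int
    keypoints: np.ndarray  # flat, length 3k, float64
    num_keypoints: int
    bbox: tuple[float, float, float, float]

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float).ravel()

    @property
    def points(self) -> np.ndarray:
        """(k, 2) array of landmark coordinates in pixels, top-left origin."""
        return self.keypoints.reshape(-1, 3)[:, :2].copy()

    @property
    def visibility(self) -> np.ndarray:
        return self.keypoints.reshape(-1, 3)[:, 2].copy()

    def validate(self) -> None:
        rid = self.image_id
        if len(self.keypoints) != 3 * self.num_keypoints:
            raise AnnotationValidationError(
                f"record id={rid}: keypoints length {len(self.keypoints)} != "
                f"3 * num_keypoints = {3 * self.num_keypoints}"
            )
        pts = self.points
        if pts.size:
            if (pts[:, 0] < 0).any() or (pts[:, 0] > self.width).any():
                raise AnnotationValidationError(
                    f"record id={rid}: x coordinate outside [0, {self.width}]"
                )
            if (pts[:, 1] < 0).any() or (pts[:, 1] > self.height).any():
                raise AnnotationValidationError(
                    f"record id={rid}: y coordinate outside [0, {self.height}]"
                )
        x0, y0, bw, bh = self.bbox
        if bw <= 0 or bh <= 0:
            raise AnnotationValidationError(
                f"record id={rid}: bbox has non-positive size ({bw}, {bh})"
            )
        if x0 < 0 or y0 < 0 or x0 + bw > self.width or y0 + bh > self.height:
            raise AnnotationValidationError(
                f"record id={rid}: bbox {self.bbox} extends outside the "
                f"{self.width}x{self.height} image"
            )


@dataclass
class LandmarkSet:
    """K ordered landmarks with names and the reference pair for normalization.

    Landmark numbering is 1-based externally (matching the anatomical
    numbering); ``reference_pair`` uses 1-based indices, default (1, 18) —
    humeral plate to the distal point of RA1, spanning the wing's long axis.
    """

    points: np.ndarray  # (K, 2)
    names: tuple[str, ...] | None = None
    reference_pair: tuple[int, int] = (1, 18)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        k = len(self.points)
        if k < 2:
            raise ValueError(f"a LandmarkSet needs at least 2 points, got {k}")
        i, j = self.reference_pair
        if i == j or not (1 <= i <= k) or not (1 <= j <= k):
            raise ValueError(
                f"reference_pair {self.reference_pair} invalid for K={k}"
            )
        if self.names is not None and len(self.names) != k:
            raise ValueError("names length must equal the number of points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DatasetIndex:
    """An ordered collection of annotations sharing one landmark count."""

    annotations: list[WingAnnotation]
    landmark_count: int | None
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def by_id(self, image_id: int) -> WingAnnotation:
        for ann in self.annotations:
            if ann.image_id == image_id:
                return ann
        raise KeyError(image_id)

    def ids(self) -> list[int]:
        return [a.image_id for a in self.annotations]

    def subset(self, ids) -> "DatasetIndex":
        wanted = list(ids)
        return DatasetIndex(
            annotations=[self.by_id(i) for i in wanted],
            landmark_count=self.landmark_count,
            source_path=self.source_path,
        )


def convert_measurement_origin(
    x: float, y_measured: float, image_height: float
) -> tuple[float, float]:
    """Map a lower-left-origin measurement to the stored top-left origin.

    The conversion is its own inverse: applying it twice returns the input.
    """
    if not 0 <= y_measured <= image_height:
        raise ValueError(
            f"y_measured={y_measured} outside [0, {image_height}]"
        )
    return x, image_height - y_measured


def reference_distance(landmarks: LandmarkSet) -> float:
    """Euclidean distance between the reference landmark pair, in pixels."""
    i, j = landmarks.reference_pair
    p, q = landmarks.points[i - 1], landmarks.points[j - 1]
    d = math.hypot(p[0] - q[0], p[1] - q[1])
    if d == 0.0:
        raise DegenerateReferenceError(
            f"reference landmarks {i} and {j} coincide at {tuple(p)}"
        )
    return d


def bbox_from_keypoints(
    points: np.ndarray,
    width: float,
    height: float,
    pad_fraction: float = 0.05,
) -> tuple[float, float, float, float]:
    """Tight box around the keypoints, padded by a fraction of its size and
    clipped to the image."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    px = (x1 - x0) * pad_fraction
    py = (y1 - y0) * pad_fraction
    x0 = max(0.0, x0 - px)
    y0 = max(0.0, y0 - py)
    x1 = min(float(width), x1 + px)
    y1 = min(float(height), y1 + py)
    return (x0, y0, x1 - x0, y1 - y0)


def landmarks_from_annotation(
    ann: WingAnnotation, reference_pair: tuple[int, int] = (1, 18)
) -> LandmarkSet:
    """View an annotation's keypoints as a LandmarkSet."""
    names = (
        HINDWING_LANDMARK_NAMES if ann.num_keypoints == len(HINDWING_LANDMARK_NAMES) else None
    )
    return LandmarkSet(points=ann.points, names=names, reference_pair=reference_pair)


__all__.append("landmarks_from_annotation")


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise CocoParseError(f"{where}: missing required field '{key}'")
    return obj[key]


def load_dataset(path: str | Path) -> DatasetIndex:
    """Load and validate a wing keypoint dataset from COCO-style JSON.

    Image and annotation records are joined on ``image_id``; every invariant
    (keypoint array length, coordinates inside the image, positive bbox) is
    checked and violations raise errors naming the offending record.  A bbox
    missing from a record is replaced by a tight padded box around its
    keypoints.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CocoParseError(f"{path}: not valid JSON ({exc})") from exc
    images = _require(doc, "images", str(path))
    raw_annotations = _require(doc, "annotations", str(path))

    image_by_id: dict[int, dict] = {}
    for img in images:
        iid = _require(img, "id", "image record")
        if iid in image_by_id:
            raise CocoParseError(f"duplicate image id {iid}")
        image_by_id[iid] = img

    annotations: list[WingAnnotation] = []
    seen_ids: set[int] = set()
    k_shared: int | None = None
    for raw in raw_annotations:
        iid = _require(raw, "image_id", "annotation record")
        if iid not in image_by_id:
            raise CocoParseError(f"annotation references unknown image id {iid}")
        if iid in seen_ids:
            raise CocoParseError(f"duplicate annotation for image id {iid}")
        seen_ids.add(iid)
        img = image_by_id[iid]
        keypoints = np.asarray(_require(raw, "keypoints", f"annotation id={iid}"), dtype=float)
        num_keypoints = int(_require(raw, "num_keypoints", f"annotation id={iid}"))
        width = int(_require(img, "width", f"image id={iid}"))
        height = int(_require(img, "height", f"image id={iid}"))
        if len(keypoints) != 3 * num_keypoints:
            raise AnnotationValidationError(
                f"record id={iid}: keypoints length {len(keypoints)} != "
                f"3 * num_keypoints = {3 * num_keypoints}"
            )
        if "bbox" in raw and raw["bbox"] is not None:
            bbox = tuple(float(v) for v in raw["bbox"])
        else:
            bbox = bbox_from_keypoints(keypoints.reshape(-1, 3)[:, :2], width, height)
        ann = WingAnnotation(
            image_id=iid,
            file_name=str(_require(img, "file_name", f"image id={iid}")),
            width=width,
            height=height,
            keypoints=keypoints,
            num_keypoints=num_keypoints,
            bbox=bbox,
        )
        ann.validate()
        if k_shared is None:
            k_shared = ann.num_keypoints
        elif ann.num_keypoints != k_shared:
            raise AnnotationValidationError(
                f"record id={iid}: num_keypoints {ann.num_keypoints} differs "
                f"from the dataset's {k_shared}"
            )
        annotations.append(ann)

    if not annotations:
        warnings.warn(f"{path}: dataset contains no annotations", stacklevel=2)
    return DatasetIndex(
        annotations=annotations, landmark_count=k_shared, source_path=str(path)
    )


def save_dataset(index: DatasetIndex, path: str | Path) -> None:
    """Write a dataset back to COCO-style JSON (round-trips with load)."""
    for ann in index.annotations:
        ann.validate()
    ids = index.ids()
    if len(set(ids)) != len(ids):
        raise AnnotationValidationError("duplicate image ids in index")
    doc = {
        "images": [
            {
                "id": a.image_id,
                "file_name": a.file_name,
                "width": a.width,
                "height": a.height,
            }
            for a in index.annotations
        ],
        "annotations": [
            {
                "id": i,
                "image_id": a.image_id,
                "keypoints": a.keypoints.tolist(),
                "num_keypoints": a.num_keypoints,
                "bbox": list(a.bbox),
            }
            for i, a in enumerate(index.annotations)
        ],
        "categories": [
            {
                "id": 1,
                "name": "hindwing",
                "keypoints": [f"landmark_{i + 1}" for i in range(index.landmark_count or 0)],
            }
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
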