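"""Procedural generator of wing-like images with exact landmark ground truth.

Each sample is rendered from a canonical template of 36 landmarks laid out
along stylized vein paths — an anterior margin chain, a radial-cell
cluster, distal vein tips, a medial chain and a cubitus-anal cluster,
mirroring the regional anatomy of a beetle hindwing.  Per-sample landmark
jitter, a random affine deformation and domain-specific texture produce the
images; the stored annotations are the exact post-deformation coordinates,
so the rendering step introduces no annotation error.

Two visual domains share identical landmark geometry:

* ``source`` — high-contrast dark veins on a clean light background, the
  pretraining corpus;
* ``target`` — low-contrast veins on a darker, textured background with
  extra noise, emulating the domain gap a model pretrained elsewhere must
  bridge when fine-tuned on real wing photographs.

Landmarks in the cubitus-anal and distal regions receive elevated jitter
and their veins reduced contrast (the most variable wing region and the
membranized distal traces are the hardest landmarks in practice);
:func:`region_difficulty` exposes the multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFilter

from .coco_io import (
    DatasetIndex,
    WingAnnotation,
    bbox_from_keypoints,
    save_dataset,
)

__all__ = [
    "WingTemplate",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_template",
    "region_difficulty",
    "generate_sample",
    "generate_dataset",
]

# canonical landmark positions in the unit frame (x rightward along the
# wing's long axis, y downward); landmark 1 = proximal humeral plate,
# landmark 18 = distal RA1 tip, so the (1, 18) reference pair spans the
# long axis.
_CANONICAL = np.array(
    [
        (0.03, 0.28), (0.12, 0.25), (0.22, 0.22), (0.33, 0.18), (0.40, 0.15),  # 1-5 margin
        (0.47, 0.26), (0.50, 0.22), (0.60, 0.21), (0.60, 0.27), (0.63, 0.24),  # 6-10 radial
        (0.52, 0.28), (0.55, 0.31), (0.67, 0.20), (0.70, 0.24), (0.70, 0.30),  # 11-15 radial
        (0.66, 0.28),                                                          # 16 radial
        (0.93, 0.30), (0.97, 0.22), (0.90, 0.38),                              # 17-19 distal tips
        (0.72, 0.42), (0.66, 0.36), (0.48, 0.36), (0.42, 0.47), (0.52, 0.44),  # 20-24 medial
        (0.57, 0.50), (0.46, 0.52),                                            # 25-26 medial
        (0.16, 0.60), (0.24, 0.65), (0.28, 0.78), (0.32, 0.62), (0.52, 0.68),  # 27-31 cubitus-anal
        (0.40, 0.60), (0.38, 0.68), (0.45, 0.74), (0.12, 0.72), (0.20, 0.85),  # 32-36 cubitus-anal
    ]
)

_REGIONS = (
    ["margin"] * 5 + ["radial"] * 11 + ["distal"] * 3 + ["medial"] * 7 + ["cubitus_anal"] * 10
)

# vein segments drawn between landmarks (1-based index pairs)
_EDGES = [
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 7),
    (7, 8), (8, 13), (13, 18), (13, 14), (14, 15), (15, 16), (16, 14),
    (7, 11), (11, 9), (9, 8), (10, 21), (12, 22), (22, 11), (17, 14), (19, 15),
    (21, 20), (20, 24), (24, 23), (24, 25), (23, 26), (26, 25), (22, 23),
    (2, 27), (27, 28), (28, 30), (30, 32), (32, 33), (33, 34), (28, 29),
    (27, 35), (35, 36), (29, 36), (31, 34), (32, 24),
]


@dataclass
class WingTemplate:
    """Mean landmark geometry, drawable vein segments and region tags."""

    canonical_points: np.ndarray  # (K, 2) in the unit frame
    vein_edges: list[tuple[int, int]]  # 1-based landmark index pairs
    region_labels: list[str]
    reference_pair: tuple[int, int] = (1, 18)

    def __post_init__(self):
        self.canonical_points = np.asarray(self.canonical_points, dtype=float)
        k = len(self.canonical_points)
        if len(self.region_labels) != k:
            raise ValueError("one region label per landmark required")
        if (self.canonical_points < 0).any() or (self.canonical_points > 1).any():
            raise ValueError("canonical points must lie in the unit frame")
        for a, b in self.vein_edges:
            if not (1 <= a <= k and 1 <= b <= k):
                raise ValueError(f"vein edge ({a}, {b}) references invalid landmarks")

    @property
    def num_landmarks(self) -> int:
        return len(self.canonical_points)


def default_template() -> WingTemplate:
    """The 36-landmark hindwing-like template."""
    return WingTemplate(
        canonical_points=_CANONICAL.copy(),
        vein_edges=list(_EDGES),
        region_labels=list(_REGIONS),
    )


@dataclass
class GeneratorConfig:
    """Rendering and deformation parameters.

    ``shape_noise`` is the per-landmark Gaussian jitter std in unit-frame
    units (multiplied per region by :func:`region_difficulty`); the affine
    deformation draws rotation (degrees), isotropic log-scale, shear and
    translation uniformly from symmetric ranges.  ``domain`` switches the
    texture preset.
    """

    image_size: int = 256
    shape_noise: float = 0.008
    rotation_deg: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    shear: float = 0.06
    translation: float = 0.03
    domain: str = "source"
    seed: int = 0
    vein_width: float = 1.8
    hard_region_multiplier: float = 2.5
    distal_multiplier: float = 2.0
    margin_multiplier: float = 1.0
    max_retries: int = 20

    def __post_init__(self):
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.shape_noise < 0:
            raise ValueError("shape_noise must be non-negative")


#: per-domain texture presets: background level, vein level, pixel noise std
_DOMAIN_TEXTURE = {
    "source": {"background": 235.0, "vein": 25.0, "noise": 3.0, "blotch": 0.0, "blur": 0.0},
    "target": {"background": 150.0, "vein": 95.0, "noise": 8.0, "blotch": 14.0, "blur": 0.8},
}


def region_difficulty(
    config: GeneratorConfig, template: WingTemplate | None = None
) -> np.ndarray:
    """Per-landmark jitter multipliers; radial/medial landmarks are baseline
    1.0, cubitus-anal and distal landmarks elevated."""
    template = template or default_template()
    table = {
        "radial": 1.0,
        "medial": 1.0,
        "margin": config.margin_multiplier,
        "distal": config.distal_multiplier,
        "cubitus_anal": config.hard_region_multiplier,
    }
    try:
        return np.array([table[r] for r in template.region_labels])
    except KeyError as exc:
        raise ValueError(f"unknown region label {exc.args[0]!r}") from None


def _sample_affine(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    theta = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    s = rng.uniform(*config.scale_range)
    shear = rng.uniform(-config.shear, config.shear)
    tx, ty = rng.uniform(-config.translation, config.translation, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    a = s * rot @ shr
    return np.array([[a[0, 0], a[0, 1], tx], [a[1, 0], a[1, 1], ty]])


def _deform(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    centered = points - 0.5
    return (centered @ affine[:, :2].T) + affine[:, 2] + 0.5


def _hard_edge(template: WingTemplate, edge: tuple[int, int]) -> bool:
    a, b = edge
    labels = template.region_labels
    return {labels[a - 1], labels[b - 1]} & {"cubitus_anal", "distal"} != set()


def _smooth_field(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    """Low-frequency blotchy texture: coarse noise bilinearly upsampled."""
    coarse = rng.normal(0.0, amplitude, size=(8, 8)).astype(np.float32)
    im = Image.fromarray(coarse, mode="F").resize((size, size), Image.BILINEAR)
    return np.asarray(im)


def generate_sample(
    template: WingTemplate,
    config: GeneratorConfig,
    sample_seed: int,
) -> tuple[np.ndarray, WingAnnotation]:
    """Render one wing image and its exact annotation.

    Deterministic in (config.seed, sample_seed).  If the sampled deformation
    pushes any landmark out of frame the draw is retried a bounded number of
    times, then an error is raised.
    """
    size = config.image_size
    mult = region_difficulty(config, template)
    base_rng = np.random.default_rng([config.seed, sample_seed])
    frame_pts = None
    for _attempt in range(config.max_retries):
        rng = np.random.default_rng(base_rng.integers(0, 2**31))
        jitter = rng.normal(0.0, config.shape_noise, size=template.canonical_points.shape)
        pts = template.canonical_points + jitter * mult[:, None]
        pts = _deform(pts, _sample_affine(rng, config))
        # map unit frame into the image with an 8% border
        px = (0.08 + 0.84 * pts) * size
        if (px > 2).all() and (px < size - 2).all():
            frame_pts = px
            texture_rng = rng
            break
    if frame_pts is None:
        raise RuntimeError(
            f"deformation kept pushing landmarks out of frame after "
            f"{config.max_retries} retries (sample_seed={sample_seed})"
        )

    tex = _DOMAIN_TEXTURE[config.domain]
    ss = 2  # supersampling factor for anti-aliased veins
    canvas = Image.new("F", (size * ss, size * ss), color=tex["background"])
    draw = ImageDraw.Draw(canvas)
    width = max(1, int(round(config.vein_width * ss)))
    for edge in template.vein_edges:
        a, b = edge
        level = tex["vein"]
        if _hard_edge(template, edge):
            # degenerate/membranized veins: pull toward the background
            level = tex["vein"] + 0.55 * (tex["background"] - tex["vein"])
        p, q = frame_pts[a - 1] * ss, frame_pts[b - 1] * ss
        draw.line([tuple(p), tuple(q)], fill=level, width=width)
    img = canvas.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32)
    if tex["blur"] > 0:  # GaussianBlur needs an integer mode
        blurred = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))
        arr = np.asarray(
            blurred.filter(ImageFilter.GaussianBlur(tex["blur"])), dtype=np.float32
        )
    if tex["blotch"] > 0:
        arr = arr + _smooth_field(texture_rng, size, tex["blotch"])
    arr = arr + texture_rng.normal(0.0, tex["noise"], size=arr.shape)
    image = np.clip(arr, 0, 255).astype(np.uint8)

    keypoints = np.concatenate(
        [frame_pts, np.full((template.num_landmarks, 1), 2.0)], axis=1
    ).ravel()
    ann = WingAnnotation(
        image_id=sample_seed,
        file_name=f"wing_{sample_seed:05d}.png",
        width=size,
        height=size,
        keypoints=keypoints,
        num_keypoints=template.num_landmarks,
        bbox=bbox_from_keypoints(frame_pts, size, size),
    )
    ann.validate()
    return image, ann


@dataclass
class SyntheticDataset:
    """In-memory dataset: annotation index plus the rendered images."""

    index: DatasetIndex
    images: dict[int, np.ndarray]

    def samples(self, ids=None) -> list[tuple[np.ndarray, WingAnnotation]]:
        wanted = list(ids) if ids is not None else self.index.ids()
        return [(self.images[i], self.index.by_id(i)) for i in wanted]

    def __len__(self) -> int:
        return len(self.index)


def generate_dataset(
    template: WingTemplate,
    config: GeneratorConfig,
    n: int = 256,
    out_dir: str | Path | None = None,
    start_id: int = 0,
    force: bool = False,
) -> SyntheticDataset:
    """Generate ``n`` samples with unique ids; optionally write them to disk.

    With ``out_dir`` the images go to ``<out_dir>/images/*.png`` and the
    annotations to ``<out_dir>/annotations.json`` in the COCO dialect; a
    non-empty existing directory is refused unless ``force``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
    images: dict[int, np.ndarray] = {}
    annotations = []
    for i in range(n):
        sid = start_id + i
        image, ann = generate_sample(template, config, sample_seed=sid)
        ann.file_name = f"images/{ann.file_name}"
        images[sid] = image
        annotations.append(ann)
        if out_dir is not None:
            Image.fromarray(image).save(out_dir / ann.file_name)
    index = DatasetIndex(
        annotations=annotations,
        landmark_count=template.num_landmarks,
        source_path=str(out_dir or "<memory>"),
    )
    if out_dir is not None:
        save_dataset(index, out_dir / "annotations.json")
    return SyntheticDataset(index=index, images=images)
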