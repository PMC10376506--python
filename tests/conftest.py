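import numpy as np
import pytest

from wingmark.coco_io import DatasetIndex, WingAnnotation, bbox_from_keypoints
from wingmark.synthetic import GeneratorConfig, default_template, generate_dataset


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def small_source_dataset(template):
    """Eight 64-px source-domain wings, shared across tests."""
    cfg = GeneratorConfig(domain="source", seed=11, image_size=64)
    return generate_dataset(template, cfg, n=8)


def make_synthetic_index(n: int, k: int = 36, size: int = 256, seed: int = 0) -> DatasetIndex:
    """Lightweight annotation-only index (no rendering) for split/protocol tests."""
    rng = np.random.default_rng(seed)
    annotations = []
    for i in range(n):
        pts = rng.uniform(20, size - 20, size=(k, 2))
        kp = np.concatenate([pts, np.full((k, 1), 2.0)], axis=1).ravel()
        annotations.append(
            WingAnnotation(
                image_id=i,
                file_name=f"images/wing_{i:05d}.png",
                width=size,
                height=size,
                keypoints=kp,
                num_keypoints=k,
                bbox=bbox_from_keypoints(pts, size, size),
            )
        )
    return DatasetIndex(annotations=annotations, landmark_count=k, source_path="<synthetic>")


@pytest.fixture(scope="session")
def index_256():
    return make_synthetic_index(256)
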