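"""Training protocol: Adam with a stepped learning-rate schedule, and the
test/training-group split plan for sample-size experiments.

The schedule is piecewise constant: the base rate of 1e-4 until epoch 40,
1e-5 from epoch 40, 1e-6 from epoch 55; training runs a fixed 80 epochs at
batch size 8 unless configured otherwise.  Epochs are 0-based, and a drop
"at epoch e" takes effect from the first batch of epoch e.

The split protocol draws a fixed-size test set (80 samples by default)
first, then, for each training-set size in (1, 3, 5, 10, 50, 100), draws 10
groups independently from the remaining pool.  Groups of the same size may
overlap one another — with 176 remaining samples, 10 disjoint groups of 100
are impossible — but never the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coco_io import DatasetIndex, WingAnnotation, landmarks_from_annotation
from .codec import CodecConfig, crop_window, encode, extract_input
from .hrnet import HRNet
from .nn import Adam, mse
from .transfer import TransferStrategy, apply_strategy, trainable_parameters

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "lr_at",
    "make_splits",
    "train",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, stepped schedule)."""

    base_lr: float = 1e-4
    lr_drops: dict[int, float] = field(default_factory=lambda: {40: 1e-5, 55: 1e-6})
    batch_size: int = 8
    max_epochs: int = 80
    seed: int = 0
    betas: tuple[float, float] = (0.9, 0.999)
    augment: bool = False  # horizontal flips; off to keep runs reproducible

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        drops = sorted(self.lr_drops)
        if any(e >= self.max_epochs or e <= 0 for e in drops):
            raise ValueError("drop epochs must lie strictly inside (0, max_epochs)")
        values = [self.base_lr] + [self.lr_drops[e] for e in drops]
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError("learning-rate schedule must be non-increasing")


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a (0-based) epoch under the stepped schedule."""
    if not 0 <= epoch < config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs})")
    lr = config.base_lr
    for e in sorted(config.lr_drops):
        if epoch >= e:
            lr = config.lr_drops[e]
    return lr


@dataclass
class SplitPlan:
    """Test ids plus training groups keyed by (size, group index)."""

    test_ids: list[int]
    group_sizes: tuple[int, ...]
    groups_per_size: int
    group_memberships: dict[tuple[int, int], list[int]]
    seed: int

    def group(self, size: int, index: int) -> list[int]:
        return list(self.group_memberships[(size, index)])

    def to_json(self) -> str:
        """Canonical serialization (byte-identical for equal seeds/inputs)."""
        doc = {
            "seed": self.seed,
            "test_ids": self.test_ids,
            "group_sizes": list(self.group_sizes),
            "groups_per_size": self.groups_per_size,
            "groups": {
                f"{size}/{idx}": ids
                for (size, idx), ids in sorted(self.group_memberships.items())
            },
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def make_splits(
    index: DatasetIndex,
    test_count: int = 80,
    group_sizes: tuple[int, ...] = (1, 3, 5, 10, 50, 100),
    groups_per_size: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Draw the test set, then the training groups, deterministically.

    Each group is a without-replacement draw from the non-test pool,
    independent across groups.
    """
    ids = index.ids()
    needed = test_count + max(group_sizes)
    if len(ids) < needed:
        raise ValueError(
            f"dataset has {len(ids)} samples; need at least {needed} "
            f"({test_count} test + largest group {max(group_sizes)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    test_ids = [ids[i] for i in order[:test_count]]
    pool = [ids[i] for i in order[test_count:]]
    memberships: dict[tuple[int, int], list[int]] = {}
    for size in group_sizes:
        for g in range(groups_per_size):
            pick = rng.choice(len(pool), size=size, replace=False)
            memberships[(size, g)] = [pool[i] for i in pick]
    return SplitPlan(
        test_ids=test_ids,
        group_sizes=tuple(group_sizes),
        groups_per_size=groups_per_size,
        group_memberships=memberships,
        seed=seed,
    )


def _prepare_sample(
    image: np.ndarray, ann: WingAnnotation, codec: CodecConfig, in_channels: int
):
    landmarks = landmarks_from_annotation(ann)
    window = crop_window(ann.bbox, codec)
    x = extract_input(image, window, codec)
    if x.shape[0] == 1 and in_channels == 3:
        x = np.repeat(x, 3, axis=0)
    elif x.shape[0] == 3 and in_channels == 1:
        x = x.mean(axis=0, keepdims=True)
    target = encode(landmarks, ann.bbox, codec).values.astype(np.float32)
    return x, target


def train(
    model: HRNet,
    samples: list[tuple[np.ndarray, WingAnnotation]],
    config: TrainConfig,
    strategy: TransferStrategy | None = None,
    codec: CodecConfig | None = None,
) -> tuple[HRNet, dict]:
    """Optimize heatmap MSE over the given samples; returns (model, manifest).

    ``samples`` are (image array, annotation) pairs held in memory.  The
    target heatmaps are encoded once up front (no augmentation by default).
    The manifest records the seed, strategy, schedule and per-epoch losses.
    """
    if not samples:
        raise ValueError("training group is empty")
    if codec is None:
        codec = CodecConfig(
            input_size=model.config.input_size,
            heatmap_size=model.config.heatmap_size(),
        )
    if codec.input_size != tuple(model.config.input_size):
        raise ValueError("codec input_size must match the model input size")
    if strategy is not None:
        apply_strategy(model, strategy)

    prepared = [
        _prepare_sample(img, ann, codec, model.config.in_channels)
        for img, ann in samples
    ]
    inputs = np.stack([p[0] for p in prepared])
    targets = np.stack([p[1] for p in prepared])

    rng = np.random.default_rng(config.seed)
    params = trainable_parameters(model)
    optimizer = Adam(params, lr=config.base_lr, betas=config.betas)
    model.train()

    n = len(prepared)
    bs = min(config.batch_size, n)
    epoch_losses: list[float] = []
    for epoch in range(config.max_epochs):
        optimizer.lr = lr_at(epoch, config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb = inputs[idx]
            tb = targets[idx]
            if config.augment and rng.random() < 0.5:
                xb = xb[:, :, :, ::-1].copy()
                tb = tb[:, :, :, ::-1].copy()
            optimizer.zero_grad()
            loss = mse(model(xb), tb)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={optimizer.lr}); "
                    "check input scaling or lower the learning rate"
                )
            loss.backward()
            optimizer.step()
            losses.append(value)
        epoch_losses.append(float(np.mean(losses)))

    manifest = {
        "seed": config.seed,
        "strategy": strategy.to_dict() if strategy is not None else None,
        "schedule": {
            "base_lr": config.base_lr,
            "lr_drops": {str(k): v for k, v in sorted(config.lr_drops.items())},
            "batch_size": config.batch_size,
            "max_epochs": config.max_epochs,
        },
        "n_samples": n,
        "epoch_losses": epoch_losses,
        "final_loss": epoch_losses[-1],
    }
    model.eval()
    return model, manifest
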