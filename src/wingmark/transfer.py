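"""Parameter-transfer strategies: checkpoint loading and stage freezing.

A trained backbone's weights can be carried into a new model while the
heatmap head is re-initialized randomly (the head's task — which landmarks,
how many — differs between source and target).  Three named strategies
control which stages are then retrained on the target data:

* ``TH`` — freeze all four stages, retrain only the head;
* ``TS`` — freeze Stage 1 (a general feature layer) and retrain Stages 2-4
  plus the head;
* ``TA`` — retrain everything.

Arbitrary per-stage masks are available through ``custom``.  The stem is
grouped with Stage 1 for freezing purposes, and frozen stages also pin
their batch-normalization running statistics so a retained stage cannot
silently adapt to the new data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hrnet import GROUP_NAMES, HRNet
from .nn.modules import BatchNorm2d, Conv2d

__all__ = [
    "TransferStrategy",
    "TransferError",
    "save_checkpoint",
    "load_checkpoint",
    "load_pretrained",
    "apply_strategy",
]

_STAGE_GROUPS = ("stage1", "stage2", "stage3", "stage4")


class TransferError(RuntimeError):
    """Checkpoint/model mismatch or an invalid strategy mask."""


@dataclass(frozen=True)
class TransferStrategy:
    """A named freeze/retrain mask over {stem, stage1..4, head}.

    True means the group is retrained; the head is always trainable.
    """

    name: str
    trainable_mask: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.trainable_mask) - set(GROUP_NAMES)
        if unknown:
            raise TransferError(f"unknown parameter groups in mask: {sorted(unknown)}")
        missing = set(GROUP_NAMES) - set(self.trainable_mask)
        if missing:
            raise TransferError(f"mask missing groups: {sorted(missing)}")
        if not self.trainable_mask["head"]:
            raise TransferError("the heatmap head must always be trainable")

    @staticmethod
    def _mask(stages: dict[str, bool]) -> dict[str, bool]:
        mask = dict(stages)
        mask["stem"] = stages["stage1"]  # stem freezes with stage 1
        mask["head"] = True
        return mask

    @classmethod
    def TH(cls) -> "TransferStrategy":
        """Head only: all four stages retained."""
        return cls("TH", cls._mask({g: False for g in _STAGE_GROUPS}))

    @classmethod
    def TS(cls) -> "TransferStrategy":
        """Stage 1 retained as a general feature layer; Stages 2-4 retrained."""
        stages = {g: g != "stage1" for g in _STAGE_GROUPS}
        return cls("TS", cls._mask(stages))

    @classmethod
    def TA(cls) -> "TransferStrategy":
        """Everything retrained."""
        return cls("TA", cls._mask({g: True for g in _STAGE_GROUPS}))

    @classmethod
    def custom(cls, stage_mask: dict[str, bool]) -> "TransferStrategy":
        """Any per-stage mask; the stem follows stage1 unless given explicitly."""
        unknown = set(stage_mask) - set(GROUP_NAMES)
        if unknown:
            raise TransferError(f"unknown parameter groups: {sorted(unknown)}")
        mask = {g: stage_mask.get(g, True) for g in _STAGE_GROUPS}
        full = cls._mask(mask)
        if "stem" in stage_mask:
            full["stem"] = stage_mask["stem"]
        if "head" in stage_mask:
            full["head"] = stage_mask["head"]
        return cls("custom", full)

    @classmethod
    def by_name(cls, name: str) -> "TransferStrategy":
        try:
            return {"TH": cls.TH, "TS": cls.TS, "TA": cls.TA}[name]()
        except KeyError:
            raise TransferError(f"unknown strategy {name!r}; use TH, TS, TA or custom")

    def frozen_groups(self) -> list[str]:
        return [g for g in GROUP_NAMES if not self.trainable_mask[g]]

    def to_dict(self) -> dict:
        return {"name": self.name, "trainable_mask": dict(self.trainable_mask)}


# ---------------------------------------------------------------------------
# checkpoints: flat name->array maps in NPZ with a JSON metadata entry


def save_checkpoint(model: HRNet, path: str | Path, extra_meta: dict | None = None) -> None:
    arrays = {f"param/{n}": p.data for n, p in model.named_parameters()}
    for n, (owner, attr) in model.named_buffers():
        arrays[f"buffer/{n}"] = owner._buffers[attr]
    meta = {"config": model.config.to_dict()}
    if extra_meta:
        meta.update(extra_meta)
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Returns (flat array map with 'param/' and 'buffer/' keys, metadata)."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files if k != "meta"}
        meta = json.loads(bytes(npz["meta"]).decode()) if "meta" in npz.files else {}
    return arrays, meta


def _reinit_head(model: HRNet, seed: int, std: float = 0.001) -> None:
    rng = np.random.default_rng(seed)
    for mod in model.head.modules():
        if isinstance(mod, Conv2d):
            mod.weight.data = rng.normal(0.0, std, size=mod.weight.shape).astype(np.float32)
            if mod.bias is not None:
                mod.bias.data = np.zeros(mod.bias.shape, dtype=np.float32)
        elif isinstance(mod, BatchNorm2d):
            mod.gamma.data = np.ones(mod.gamma.shape, dtype=np.float32)
            mod.beta.data = np.zeros(mod.beta.shape, dtype=np.float32)
            mod.running_mean[:] = 0.0
            mod.running_var[:] = 1.0


def load_pretrained(
    model: HRNet,
    checkpoint: str | Path | tuple[dict, dict],
    head_seed: int = 0,
    strict_backbone: bool = True,
) -> HRNet:
    """Load backbone weights from a checkpoint; re-initialize the head.

    Backbone groups (stem, stage1-4) must match the checkpoint shape-for-
    shape; a mismatch raises :class:`TransferError` naming the group.  Head
    entries present in the checkpoint are ignored with a warning.  Head conv
    weights are drawn from normal(0, 0.001), biases zeroed, using
    ``head_seed`` (recorded by the trainer in its run manifest).
    """
    if isinstance(checkpoint, (str, Path)):
        arrays, _meta = load_checkpoint(checkpoint)
    else:
        arrays, _meta = checkpoint

    from .hrnet import parameter_group_of

    if any(k.startswith("param/head") for k in arrays):
        warnings.warn("checkpoint contains head parameters; ignored", stacklevel=2)

    params = dict(model.named_parameters())
    for name, p in params.items():
        group = parameter_group_of(name)
        if group == "head":
            continue
        key = f"param/{name}"
        if key not in arrays:
            if strict_backbone:
                raise TransferError(f"group '{group}': checkpoint missing parameter {name}")
            continue
        value = arrays[key]
        if value.shape != p.data.shape:
            raise TransferError(
                f"group '{group}': shape mismatch for {name} "
                f"(checkpoint {value.shape}, model {p.data.shape})"
            )
        p.data = value.astype(np.float32).copy()
    for name, (owner, attr) in model.named_buffers():
        if parameter_group_of(name) == "head":
            continue
        key = f"buffer/{name}"
        if key in arrays:
            owner._buffers[attr][:] = arrays[key]

    _reinit_head(model, seed=head_seed)
    return model


def apply_strategy(
    model: HRNet,
    strategy: TransferStrategy,
    freeze_bn_stats: bool = True,
) -> HRNet:
    """Mark frozen groups untrainable; optimizers then skip them entirely.

    With ``freeze_bn_stats`` (default) the running statistics of batch
    normalization inside frozen groups are pinned to their loaded values, so
    a retained stage is bit-stable under any amount of further training.
    """
    groups = model.parameter_groups()
    for group, entries in groups.items():
        trainable = strategy.trainable_mask[group]
        for _name, p in entries:
            p.requires_grad = trainable
        if freeze_bn_stats:
            for bn in model.group_batchnorms(group):
                bn.frozen_stats = not trainable
    return model


def trainable_parameters(model: HRNet) -> list:
    """The parameters an optimizer should update under the applied strategy."""
    return [p for p in model.parameters() if p.requires_grad]


__all__.append("trainable_parameters")
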