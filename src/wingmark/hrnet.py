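"""A multi-resolution heatmap-regression backbone for landmark detection.

The network keeps a high-resolution branch throughout and grows parallel
half-resolution, double-channel branches stage by stage:

* a stem of two stride-2 3x3 convolutions brings the input to 1/4 resolution;
* Stage 1 runs four bottleneck residual blocks on a single branch;
* Stages 2-4 run basic residual blocks on 2/3/4 parallel branches, with a
  fusion module after every group of basic blocks — 1, 4 and 3 fusions in
  Stages 2, 3 and 4 respectively;
* a representation head upsamples the three low-resolution maps to the
  high-resolution grid, concatenates all four, and a 1x1 heatmap head emits
  one channel per landmark at 1/4 of the input resolution.

Residual units follow the standard conv configurations: bottleneck
(1x1,1,0)-(3x3,1,1)-(1x1,1,0) with a 4x channel expansion, basic
(3x3,1,1)-(3x3,1,1).  Every convolution is followed by batch normalization
and (except block outputs pre-addition) a ReLU.

Parameters partition into the named groups {stem, stage1, stage2, stage3,
stage4, head}; the transition convolutions that create each new branch are
grouped with the stage they feed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported convenience)
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    add,
    concat,
    no_grad,
    relu,
    upsample_bilinear,
)

__all__ = [
    "BackboneConfig",
    "BlockSpec",
    "BOTTLENECK_SPEC",
    "BASIC_SPEC",
    "GROUP_NAMES",
    "HRNet",
    "FusionModule",
    "build_model",
    "hwlfc_config",
    "tiny_config",
    "parameter_group_of",
]

GROUP_NAMES = ("stem", "stage1", "stage2", "stage3", "stage4", "head")

#: which top-level module prefixes belong to which freeze/transfer group;
#: each transition is grouped with the stage whose branches it creates.
_PREFIX_GROUP = {
    "stem": "stem",
    "stage1": "stage1",
    "transition1": "stage2",
    "stage2": "stage2",
    "transition2": "stage3",
    "stage3": "stage3",
    "transition3": "stage4",
    "stage4": "stage4",
    "head": "head",
}


@dataclass(frozen=True)
class BlockSpec:
    """Conv-layer layout of a residual unit: (kernel, stride, padding) triples."""

    kind: str
    conv_layers: tuple[tuple[int, int, int], ...]
    residual_projection: str = "1x1 conv when channel counts differ"


BOTTLENECK_SPEC = BlockSpec("bottleneck", ((1, 1, 0), (3, 1, 1), (1, 1, 0)))
BASIC_SPEC = BlockSpec("basic", ((3, 1, 1), (3, 1, 1)))

BOTTLENECK_EXPANSION = 4  # final 1x1 conv restores 4x the bottleneck's middle width


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count of the highest-resolution branch
    (18 for the w18 model); branch b carries ``base_width * 2**b`` channels at
    1/(4*2**b) of the input resolution.  ``fusion_counts`` gives the number of
    fusion modules in Stages 2-4 and ``blocks_per_fusion`` the basic blocks
    preceding each fusion on every branch.
    """

    base_width: int = 18
    num_landmarks: int = 36
    input_size: tuple[int, int] = (256, 256)
    in_channels: int = 3
    stem_width: int = 64
    stage1_blocks: int = 4
    fusion_counts: tuple[int, int, int] = (1, 4, 3)
    blocks_per_fusion: int = 4

    def __post_init__(self):
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 32 "
                "(stride-4 stem plus three further halvings)"
            )
        if len(self.fusion_counts) != 3:
            raise ValueError("fusion_counts must have one entry per stage 2-4")

    def branch_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**b for b in range(4))

    def heatmap_size(self) -> tuple[int, int]:
        return (self.input_size[0] // 4, self.input_size[1] // 4)

    def to_dict(self) -> dict:
        return {
            "base_width": self.base_width,
            "num_landmarks": self.num_landmarks,
            "input_size": list(self.input_size),
            "in_channels": self.in_channels,
            "stem_width": self.stem_width,
            "stage1_blocks": self.stage1_blocks,
            "fusion_counts": list(self.fusion_counts),
            "blocks_per_fusion": self.blocks_per_fusion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        d["fusion_counts"] = tuple(d["fusion_counts"])
        return cls(**d)


def hwlfc_config(num_landmarks: int = 36) -> BackboneConfig:
    """The full-size w18 configuration used for hindwing landmark detection."""
    return BackboneConfig(num_landmarks=num_landmarks)


def tiny_config(
    num_landmarks: int = 36,
    input_size: tuple[int, int] = (64, 64),
    in_channels: int = 1,
) -> BackboneConfig:
    """A reduced configuration that trains on CPU in minutes.

    Same four-stage, four-branch topology; fewer channels and blocks.
    """
    return BackboneConfig(
        base_width=8,
        num_landmarks=num_landmarks,
        input_size=input_size,
        in_channels=in_channels,
        stem_width=16,
        stage1_blocks=1,
        fusion_counts=(1, 1, 1),
        blocks_per_fusion=1,
    )


def parameter_group_of(qualified_name: str) -> str:
    """Map a qualified parameter/module name to its transfer group."""
    prefix = qualified_name.split(".", 1)[0]
    try:
        return _PREFIX_GROUP[prefix]
    except KeyError:
        raise KeyError(f"name {qualified_name!r} has no parameter group") from None


def _conv_bn(cin, cout, k, s, p, rng, with_relu=True) -> Sequential:
    mods = [Conv2d(cin, cout, k, stride=s, padding=p, bias=False, rng=rng), BatchNorm2d(cout)]
    if with_relu:
        mods.append(ReLU())
    return Sequential(*mods)


class BasicBlock(Module):
    """Residual unit (3x3,1,1)-(3x3,1,1); channel count unchanged."""

    spec = BASIC_SPEC

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv1 = _conv_bn(channels, channels, 3, 1, 1, rng)
        self.conv2 = _conv_bn(channels, channels, 3, 1, 1, rng, with_relu=False)

    def forward(self, x: Tensor) -> Tensor:
        return relu(add(self.conv2(self.conv1(x)), x))


class Bottleneck(Module):
    """Residual unit (1x1,1,0)-(3x3,1,1)-(1x1,1,0): channels reduced then
    enlarged by the expansion factor; 1x1 projection when counts differ."""

    spec = BOTTLENECK_SPEC

    def __init__(self, in_channels: int, mid_channels: int, rng):
        super().__init__()
        out_channels = mid_channels * BOTTLENECK_EXPANSION
        self.out_channels = out_channels
        self.conv1 = _conv_bn(in_channels, mid_channels, 1, 1, 0, rng)
        self.conv2 = _conv_bn(mid_channels, mid_channels, 3, 1, 1, rng)
        self.conv3 = _conv_bn(mid_channels, out_channels, 1, 1, 0, rng, with_relu=False)
        self.project = (
            _conv_bn(in_channels, out_channels, 1, 1, 0, rng, with_relu=False)
            if in_channels != out_channels
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        res = self.project(x) if self.project is not None else x
        return relu(add(self.conv3(self.conv2(self.conv1(x))), res))


class FusionModule(Module):
    """Exchange information across resolution branches.

    Each output branch is the sum over all input branches, resampled to its
    resolution: identity for the same branch, a chain of stride-2 3x3
    convolutions toward lower resolution, and a 1x1 conv + bilinear
    upsampling toward higher resolution.  A single-branch call is the
    identity.
    """

    def __init__(self, widths: list[int], rng):
        super().__init__()
        self.widths = list(widths)
        n = len(widths)
        self.paths: dict[tuple[int, int], Module] = {}
        for i in range(n):  # source branch
            for j in range(n):  # destination branch
                if i == j:
                    continue
                if i < j:  # downsample: (j - i) stride-2 3x3 convs
                    convs = []
                    for step in range(j - i):
                        last = step == j - i - 1
                        cout = widths[j] if last else widths[i]
                        convs.append(_conv_bn(widths[i], cout, 3, 2, 1, rng, with_relu=not last))
                    path = Sequential(*convs)
                else:  # upsample: 1x1 conv to match channels, then resize
                    path = _conv_bn(widths[i], widths[j], 1, 1, 0, rng, with_relu=False)
                self.paths[(i, j)] = path
                self._modules[f"path_{i}_{j}"] = path

    def forward(self, branches: list[Tensor]) -> list[Tensor]:
        n = len(branches)
        if n != len(self.widths):
            raise ValueError(f"expected {len(self.widths)} branches, got {n}")
        if n == 1:
            return list(branches)
        outs = []
        for j in range(n):
            total = None
            target_hw = branches[j].shape[2:]
            for i in range(n):
                if i == j:
                    term = branches[i]
                else:
                    term = self.paths[(i, j)](branches[i])
                    if i > j:
                        term = upsample_bilinear(term, target_hw)
                total = term if total is None else add(total, term)
            outs.append(relu(total))
        return outs


class _BranchBlocks(Module):
    """``blocks_per_fusion`` basic blocks on every branch, then one fusion."""

    def __init__(self, widths: list[int], blocks: int, rng):
        super().__init__()
        self.branches = []
        for b, w in enumerate(widths):
            seq = Sequential(*[BasicBlock(w, rng) for _ in range(blocks)])
            self.branches.append(seq)
            self._modules[f"branch{b}"] = seq
        self.fuse = FusionModule(widths, rng)

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        return self.fuse([seq(x) for seq, x in zip(self.branches, xs)])


class _Stage(Module):
    """A multi-branch stage: ``n_fusions`` repetitions of blocks + fusion."""

    def __init__(self, widths: list[int], n_fusions: int, blocks: int, rng):
        super().__init__()
        self.units = []
        for u in range(n_fusions):
            unit = _BranchBlocks(widths, blocks, rng)
            self.units.append(unit)
            self._modules[f"unit{u}"] = unit

    @property
    def fusion_modules(self) -> list[FusionModule]:
        return [u.fuse for u in self.units]

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        for unit in self.units:
            xs = unit(xs)
        return xs


class HRNet(Module):
    """The full landmark-detection network; see the module docstring."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = list(config.branch_widths())
        sw = config.stem_width

        self.stem = Sequential(
            _conv_bn(config.in_channels, sw, 3, 2, 1, rng),
            _conv_bn(sw, sw, 3, 2, 1, rng),
        )

        blocks = []
        cin = sw
        for _ in range(config.stage1_blocks):
            blk = Bottleneck(cin, sw, rng)
            cin = blk.out_channels
            blocks.append(blk)
        self.stage1 = Sequential(*blocks)
        stage1_out = cin

        # transitions create each stage's new lowest branch; existing
        # branches pass through unchanged (transition1 additionally maps the
        # bottleneck output onto the two initial branches)
        self.transition1 = Sequential(
            _conv_bn(stage1_out, widths[0], 3, 1, 1, rng),
            _conv_bn(stage1_out, widths[1], 3, 2, 1, rng),
        )
        self.stage2 = _Stage(widths[:2], config.fusion_counts[0], config.blocks_per_fusion, rng)
        self.transition2 = _conv_bn(widths[1], widths[2], 3, 2, 1, rng)
        self.stage3 = _Stage(widths[:3], config.fusion_counts[1], config.blocks_per_fusion, rng)
        self.transition3 = _conv_bn(widths[2], widths[3], 3, 2, 1, rng)
        self.stage4 = _Stage(widths, config.fusion_counts[2], config.blocks_per_fusion, rng)

        rep_width = sum(widths)
        final = Conv2d(rep_width, config.num_landmarks, 1, rng=rng)
        # small-init the output conv: near-zero initial heatmaps speed up
        # MSE regression against sparse Gaussian targets
        final.weight.data = rng.normal(0.0, 0.001, size=final.weight.shape).astype(np.float32)
        final.bias.data[:] = 0.0
        self.head = Sequential(_conv_bn(rep_width, rep_width, 1, 1, 0, rng), final)

    # -- structure introspection -------------------------------------------
    def stage1_block_count(self) -> int:
        return sum(1 for m in self.stage1 if isinstance(m, Bottleneck))

    def fusion_counts(self) -> tuple[int, int, int]:
        return (
            len(self.stage2.fusion_modules),
            len(self.stage3.fusion_modules),
            len(self.stage4.fusion_modules),
        )

    def parameter_groups(self) -> dict[str, list[tuple[str, Tensor]]]:
        """Partition all named parameters into the six transfer groups."""
        groups: dict[str, list] = {g: [] for g in GROUP_NAMES}
        for name, p in self.named_parameters():
            groups[parameter_group_of(name)].append((name, p))
        return groups

    def group_batchnorms(self, group: str):
        """Batch-normalization modules whose parameters belong to ``group``."""
        out = []
        for prefix, g in _PREFIX_GROUP.items():
            if g != group:
                continue
            mod = getattr(self, prefix)
            out.extend(m for m in mod.modules() if isinstance(m, BatchNorm2d))
        return out

    # -- forward ------------------------------------------------------------
    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[1] != self.config.in_channels or x.shape[2:] != tuple(self.config.input_size):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match config "
                f"({self.config.in_channels}, *{self.config.input_size})"
            )
        y = self.stage1(self.stem(x))
        branches = [self.transition1[0](y), self.transition1[1](y)]
        branches = self.stage2(branches)
        branches = branches + [self.transition2(branches[-1])]
        branches = self.stage3(branches)
        branches = branches + [self.transition3(branches[-1])]
        branches = self.stage4(branches)
        target_hw = branches[0].shape[2:]
        rep = concat(
            [branches[0]]
            + [upsample_bilinear(b, target_hw) for b in branches[1:]]
        )
        return self.head(rep)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference: eval mode, no tape; returns a (B, C, H, W) array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(images)
        finally:
            self.train(was_training)
        return out.data


def build_model(config: BackboneConfig, seed: int = 0) -> HRNet:
    """Construct the network with reproducible random initialization."""
    return HRNet(config, seed=seed)
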