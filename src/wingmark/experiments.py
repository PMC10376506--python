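"""Desk-scale experiment harness.

Reproduces the structure of the transfer-learning study on procedurally
generated wings: pretrain a reduced model on a source-domain corpus, then
fine-tune on a handful of target-domain samples under a chosen stage-freeze
strategy and measure NME on held-out target wings.  The quantities of
interest are comparative (transfer versus training from random
initialization), not the absolute errors of the full-scale study.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codec import CodecConfig
from .hrnet import build_model, tiny_config
from .synthetic import GeneratorConfig, default_template, generate_dataset
from .trainer import TrainConfig, train
from .transfer import TransferStrategy, load_pretrained, save_checkpoint
from .evaluator import evaluate_model

__all__ = ["ExperimentScale", "pretrain_source_model", "run_transfer_comparison"]


@dataclass
class ExperimentScale:
    """Problem sizes for the scaled-down experiment."""

    n_pretrain: int = 200
    n_finetune: int = 3
    n_test: int = 30
    pretrain_epochs: int = 10
    finetune_epochs: int = 80
    image_size: int = 64

    def codec(self) -> CodecConfig:
        s = self.image_size
        return CodecConfig(input_size=(s, s), heatmap_size=(s // 4, s // 4), sigma=2.0)


def _pretrain_schedule(scale: ExperimentScale) -> TrainConfig:
    # a faster schedule than the full-scale protocol: the tiny model sees
    # far fewer steps, so the base rate is higher and drops are proportional
    e = scale.pretrain_epochs
    drops = {}
    if e >= 4:
        drops[max(1, int(e * 0.6))] = 3e-4
    if e >= 8:
        drops[max(2, int(e * 0.85))] = 1e-4
    return TrainConfig(base_lr=1e-3, lr_drops=drops, max_epochs=e, batch_size=8)


def _finetune_schedule(scale: ExperimentScale, seed: int) -> TrainConfig:
    e = scale.finetune_epochs
    drops = {k: v for k, v in {int(e * 0.5): 3e-4, int(e * 0.7): 1e-4}.items() if 0 < k < e}
    return TrainConfig(base_lr=1e-3, lr_drops=drops, max_epochs=e, batch_size=8, seed=seed)


def pretrain_source_model(
    seed: int,
    scale: ExperimentScale | None = None,
    num_landmarks: int = 36,
    checkpoint_path=None,
):
    """Train the reduced model from scratch on source-domain wings.

    Returns (model, manifest); optionally saves a checkpoint for reuse.
    """
    scale = scale or ExperimentScale()
    template = default_template()
    src_cfg = GeneratorConfig(domain="source", seed=seed, image_size=scale.image_size)
    data = generate_dataset(template, src_cfg, n=scale.n_pretrain)
    model = build_model(
        tiny_config(num_landmarks=num_landmarks, input_size=(scale.image_size,) * 2),
        seed=seed,
    )
    model, manifest = train(
        model, data.samples(), _pretrain_schedule(scale), codec=scale.codec()
    )
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, extra_meta={"pretrain_seed": seed})
    return model, manifest


def run_transfer_comparison(
    seed: int,
    scale: ExperimentScale | None = None,
    pretrained=None,
) -> dict:
    """One seed of the small-sample transfer experiment.

    Pretrains on source-domain wings (unless a pretrained model/checkpoint
    is supplied), then fine-tunes two arms on the same ``n_finetune``
    target-domain samples: stage-1-frozen transfer (TS) versus training the
    identical architecture from random initialization.  Both arms are
    evaluated on the same held-out target wings.

    Returns a dict with ``nme_transfer``, ``nme_scratch`` and bookkeeping.
    """
    scale = scale or ExperimentScale()
    template = default_template()
    codec = scale.codec()
    k = template.num_landmarks

    if pretrained is None:
        pretrained, _ = pretrain_source_model(seed, scale, num_landmarks=k)

    tgt_train_cfg = GeneratorConfig(
        domain="target", seed=seed + 1_000_000, image_size=scale.image_size
    )
    tgt_test_cfg = GeneratorConfig(
        domain="target", seed=seed + 2_000_000, image_size=scale.image_size
    )
    train_data = generate_dataset(template, tgt_train_cfg, n=scale.n_finetune)
    test_data = generate_dataset(template, tgt_test_cfg, n=scale.n_test, start_id=10_000)
    train_samples = train_data.samples()
    test_samples = test_data.samples()

    model_cfg = tiny_config(num_landmarks=k, input_size=(scale.image_size,) * 2)

    # arm 1: transfer — pretrained backbone, fresh head, stage 1 frozen
    transfer_model = build_model(model_cfg, seed=seed + 1)
    from .hrnet import parameter_group_of

    ckpt = (
        {
            f"param/{n}": p.data
            for n, p in pretrained.named_parameters()
            if parameter_group_of(n) != "head"
        }
        | {
            f"buffer/{n}": owner._buffers[a]
            for n, (owner, a) in pretrained.named_buffers()
            if parameter_group_of(n) != "head"
        },
        {},
    )
    load_pretrained(transfer_model, ckpt, head_seed=seed + 2)
    transfer_model, _ = train(
        transfer_model,
        train_samples,
        _finetune_schedule(scale, seed),
        strategy=TransferStrategy.TS(),
        codec=codec,
    )
    report_transfer = evaluate_model(
        transfer_model, test_samples, codec, metadata={"strategy": "TS", "seed": seed}
    )

    # arm 2: identical architecture and schedule from random initialization
    scratch_model = build_model(model_cfg, seed=seed + 3)
    scratch_model, _ = train(
        scratch_model, train_samples, _finetune_schedule(scale, seed), codec=codec
    )
    report_scratch = evaluate_model(
        scratch_model, test_samples, codec, metadata={"strategy": "scratch", "seed": seed}
    )

    return {
        "seed": seed,
        "n_finetune": scale.n_finetune,
        "n_test": len(test_samples),
        "nme_transfer": report_transfer.mean_nme,
        "nme_scratch": report_scratch.mean_nme,
        "report_transfer": report_transfer,
        "report_scratch": report_scratch,
    }
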