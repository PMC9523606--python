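"""Two-stage training and evaluation orchestration.

Stage 1 (base-training) trains the encoder with a throwaway linear
classifier on image-wise batches of the base domain's training classes.
Stage 2 (meta-learning) discards the classifier, formats data as N-way
K-shot tasks and trains the same encoder through the nearest-centroid
metric head, checkpointing on best validation episode accuracy. Evaluation
samples many episodes from held-out novel classes and reports the mean
accuracy with a normal-approximation 95% confidence interval.

The five domain-transfer strategies S1-S5 plug the domains of a registry
into the (base, meta, test) stage triple; `run_strategy` executes one end
to end and logs full provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, SGD, Linear
from .encoder import Encoder, EncoderConfig
from .episodes import (
    EpisodeSpec, SplitSpec, StagePlan, batch_episodes, sample_episode,
)
from .metric import (
    MetricConfig, MetricHead, cross_entropy, episode_accuracy,
)
from .synthetic import ImageBank

__all__ = [
    "StageConfig",
    "EvalReport",
    "Standardizer",
    "base_train",
    "meta_train",
    "validate",
    "evaluate",
    "way_shot_sweep",
    "run_strategy",
    "ContaminationError",
]

logger = logging.getLogger("leafshot")


class ContaminationError(ValueError):
    """Evaluation was offered classes seen during training."""


@dataclass(frozen=True)
class StageConfig:
    """Hyper-parameters of one training stage.

    For the base stage ``batch`` is images per step; for the meta stage it
    is tasks per batch and ``episode`` gives the task geometry. ``lr_decay``
    is an optional (factor, epoch) pair applied from that epoch on.
    """

    stage: str                      # "base" | "meta"
    epochs: int
    learning_rate: float
    batch: int = 64
    lr_decay: tuple[float, int] | None = None
    episode: EpisodeSpec | None = None
    batches_per_epoch: int | None = None   # meta stage: task batches per epoch
    val_episodes: int = 200
    val_episode: EpisodeSpec | None = None  # default: 5-way 1-shot 15-query,
                                            # way capped at available classes
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("base", "meta"):
            raise ValueError("stage must be 'base' or 'meta'")
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch < 1:
            raise ValueError("epochs must be >= 0, rate and batch positive")
        if self.stage == "meta" and self.episode is None:
            raise ValueError("meta stage needs an episode spec")


@dataclass
class EvalReport:
    """Mean episode accuracy with CI; grids carry per-(N,K) cells."""

    n_tasks: int
    mean_accuracy: float
    ci95_half_width: float | None
    per_task: np.ndarray = field(repr=False, default=None)
    cells: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tasks": self.n_tasks,
            "mean_accuracy": self.mean_accuracy,
            "ci95_half_width": self.ci95_half_width,
            "cells": {
                str(k): {
                    "mean_accuracy": v.mean_accuracy,
                    "ci95_half_width": v.ci95_half_width,
                    "n_tasks": v.n_tasks,
                } for k, v in self.cells.items()
            } if self.cells else {},
            "provenance": self.provenance,
        }


@dataclass
class Standardizer:
    """Per-channel standardisation with dataset statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, bank: ImageBank) -> "Standardizer":
        m = bank.images.mean(axis=(0, 2, 3))
        s = bank.images.std(axis=(0, 2, 3))
        return cls(m.astype(np.float32), np.maximum(s, 1e-3).astype(np.float32))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return (images - self.mean.reshape(1, 3, 1, 1)) / self.std.reshape(1, 3, 1, 1)


def _lr_at(cfg: StageConfig, epoch: int) -> float:
    lr = cfg.learning_rate
    if cfg.lr_decay is not None:
        factor, at_epoch = cfg.lr_decay
        if epoch >= at_epoch:
            lr *= factor
    return lr


def base_train(
    encoder: Encoder,
    part: ImageBank,
    cfg: StageConfig,
    standardizer: Standardizer | None = None,
) -> tuple[Encoder, Linear, list[dict]]:
    """Stage 1: supervised training with a linear head over the part's
    classes; returns (encoder, head, per-epoch records). The head is meant
    to be discarded before meta-learning."""
    if cfg.stage != "base":
        raise ValueError("base_train needs a base StageConfig")
    if len(part) == 0:
        raise ValueError("empty training data")
    classes = part.class_ids
    if len(classes) < 2:
        raise ValueError("base-training needs at least 2 classes")
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([cls_index[int(c)] for c in part.labels], dtype=np.int64)
    std = standardizer or Standardizer.fit(part)
    x = std(part.images)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xBA5E])
    head = Linear(encoder.config.fused_channels, len(classes),
                  np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x4EAD]))
    opt = SGD(encoder.parameters() + head.parameters(), cfg.learning_rate,
              cfg.momentum, cfg.weight_decay)
    history: list[dict] = []
    encoder.train()
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(cfg, epoch)
        order = rng.permutation(len(x))
        losses, accs = [], []
        for i in range(0, len(order), cfg.batch):
            idx = order[i : i + cfg.batch]
            if len(idx) < 2:
                continue  # BN needs more than one sample
            emb = encoder(Tensor(x[idx]))
            logits = head(emb)
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(episode_accuracy(logits, y[idx]))
        rec = {"stage": "base", "epoch": epoch, "lr": opt.lr,
               "loss": float(np.mean(losses)), "acc": float(np.mean(accs))}
        history.append(rec)
        logger.info("base epoch %d: loss=%.4f acc=%.3f", epoch, rec["loss"], rec["acc"])
    return encoder, head, history


def _episode_pass(encoder: Encoder, mhead: MetricHead, task,
                  std: Standardizer):
    """Embed support and queries, build centroids, return (loss, acc)."""
    n = task.n_way
    k = len(task.support_labels) // n
    sup = encoder(Tensor(std(task.support_images)))
    qry = encoder(Tensor(std(task.query_images)))
    d = sup.shape[1]
    # support rows are grouped by episode label (K consecutive rows each)
    protos = sup.reshape(n, k, d).mean(axis=1)
    logits = mhead.logits(qry, protos)
    loss = cross_entropy(logits, task.query_labels)
    return loss, episode_accuracy(logits, task.query_labels)


def validate(encoder: Encoder, mhead: MetricHead, part: ImageBank,
             spec: EpisodeSpec, n_episodes: int, seed: int,
             std: Standardizer) -> float:
    """Mean episode accuracy on freshly sampled fixed-seed episodes."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x7A11])
    encoder.eval()
    accs = []
    with ad.no_grad():
        for _ in range(n_episodes):
            task = sample_episode(part, spec, rng)
            _, acc = _episode_pass(encoder, mhead, task, std)
            accs.append(acc)
    encoder.train()
    return float(np.mean(accs))


def meta_train(
    encoder: Encoder,
    mhead: MetricHead,
    part: ImageBank,
    cfg: StageConfig,
    standardizer: Standardizer,
    val_part: ImageBank | None = None,
) -> tuple[Encoder, list[dict]]:
    """Stage 2: episodic training through the metric head.

    Per batch: sample tasks, embed support, average into centroids, embed
    queries, compute scaled-similarity logits, cross-entropy, backprop.
    Returns the encoder restored to its best-validation state (or the
    final state when no validation part is given)."""
    if cfg.stage != "meta":
        raise ValueError("meta_train needs a meta StageConfig")
    if cfg.epochs == 0:
        return encoder, []
    spec = cfg.episode
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x3E7A])
    opt = SGD(encoder.parameters() + mhead.parameters(), cfg.learning_rate,
              cfg.momentum, cfg.weight_decay)
    n_classes = len(part.class_ids)
    per_class = min(len(ix) for ix in part.indices_by_class().values())
    default_batches = max(
        1, (n_classes * per_class) // (cfg.batch * spec.n_way * (spec.k_shot + spec.w_query))
    )
    batches = cfg.batches_per_epoch or default_batches
    history: list[dict] = []
    best_acc, best_state = -1.0, None
    encoder.train()
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(cfg, epoch)
        losses, accs = [], []
        for _ in range(batches):
            tasks = batch_episodes(part, spec, cfg.batch, rng)
            opt.zero_grad()
            batch_losses = []
            for task in tasks:
                loss, acc = _episode_pass(encoder, mhead, task, standardizer)
                batch_losses.append(loss)
                accs.append(acc)
            total = batch_losses[0]
            for l in batch_losses[1:]:
                total = total + l
            total = total * (1.0 / len(batch_losses))
            total.backward()
            opt.step()
            losses.append(float(total.data))
        rec = {"stage": "meta", "epoch": epoch, "lr": opt.lr,
               "loss": float(np.mean(losses)), "acc": float(np.mean(accs)),
               "gamma": mhead.gamma_value}
        if val_part is not None and len(val_part.class_ids) >= 2:
            vspec = cfg.val_episode or EpisodeSpec(
                min(5, len(val_part.class_ids)), 1, 15
            )
            rec["val_acc"] = validate(
                encoder, mhead, val_part, vspec,
                cfg.val_episodes, cfg.seed, standardizer,
            )
            # ties keep the later epoch: among equally-validating states,
            # prefer the one that meta-trained longest
            if rec["val_acc"] >= best_acc:
                best_acc = rec["val_acc"]
                best_state = copy.deepcopy(encoder.state_dict())
        history.append(rec)
        logger.info("meta epoch %d: loss=%.4f acc=%.3f%s", epoch, rec["loss"],
                    rec["acc"],
                    f" val={rec['val_acc']:.3f}" if "val_acc" in rec else "")
    if best_state is not None:
        encoder.load_state_dict(best_state)
    return encoder, history


def evaluate(
    encoder: Encoder,
    test_part: ImageBank,
    spec: EpisodeSpec,
    n_tasks: int,
    metric_config: MetricConfig,
    seed: int,
    standardizer: Standardizer | None = None,
    split: SplitSpec | None = None,
) -> EvalReport:
    """Mean accuracy over ``n_tasks`` freshly sampled test episodes.

    If a SplitSpec is supplied, refuses any test class seen in training or
    validation (contamination guard)."""
    if split is not None:
        seen = set(split.train_classes) | set(split.val_classes)
        overlap = seen & set(test_part.class_ids)
        if overlap:
            raise ContaminationError(
                f"test part contains training classes: {sorted(overlap)}"
            )
    std = standardizer or Standardizer.fit(test_part)
    mhead = MetricHead(metric_config)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xE7A1])
    encoder.eval()
    accs = np.empty(n_tasks)
    with ad.no_grad():
        for t in range(n_tasks):
            task = sample_episode(test_part, spec, rng)
            _, accs[t] = _episode_pass(encoder, mhead, task, std)
    encoder.train()
    mean = float(accs.mean())
    ci = (
        float(1.96 * accs.std(ddof=1) / np.sqrt(n_tasks)) if n_tasks > 1 else None
    )
    return EvalReport(
        n_tasks, mean, ci, per_task=accs,
        provenance={"spec": asdict(spec), "seed": seed,
                    "metric": asdict(metric_config)},
    )


def way_shot_sweep(
    encoder: Encoder,
    test_part: ImageBank,
    ways: list[int],
    shots: list[int],
    w_query: int,
    n_tasks: int,
    metric_config: MetricConfig,
    seed: int,
    standardizer: Standardizer | None = None,
) -> EvalReport:
    """Grid of evaluate() cells over (way, shot); the report's mean is the
    grand mean over cells, and `cells[(n, k)]` holds each cell's report."""
    if max(ways) > len(test_part.class_ids):
        raise ValueError("max way exceeds available classes")
    cells: dict[tuple[int, int], EvalReport] = {}
    for n in ways:
        for k in shots:
            cells[(n, k)] = evaluate(
                encoder, test_part, EpisodeSpec(n, k, w_query), n_tasks,
                metric_config, seed, standardizer,
            )
    grand = float(np.mean([c.mean_accuracy for c in cells.values()]))
    rep = EvalReport(n_tasks * len(cells), grand, None, cells=cells)
    rep.provenance = {"ways": ways, "shots": shots, "seed": seed}
    return rep


def run_strategy(
    plan: StagePlan,
    registry: dict[str, ImageBank],
    splits: dict[str, SplitSpec],
    encoder_config: EncoderConfig,
    base_cfg: StageConfig,
    meta_cfg: StageConfig,
    metric_config: MetricConfig,
    eval_spec: EpisodeSpec,
    eval_tasks: int = 200,
    eval_seed: int = 0,
    encoder_seed: int = 0,
) -> tuple[Encoder, EvalReport]:
    """Execute one strategy end to end: base-train on the plan's base
    domain, meta-train on its meta domain, evaluate on its test domain.

    ``splits`` maps a domain name to its SplitSpec; a domain used for
    testing contributes its test classes, a domain used for training its
    train (and val) classes. Provenance (plan, seeds, configs) is logged
    into the returned report."""
    for dom in (plan.base_domain, plan.meta_domain, plan.test_domain):
        if dom not in registry:
            raise KeyError(f"domain {dom!r} missing from registry")

    t0 = time.time()
    base_part = registry[plan.base_domain].subset(
        splits[plan.base_domain].train_classes
    )
    meta_split = splits[plan.meta_domain]
    meta_part = registry[plan.meta_domain].subset(meta_split.train_classes)
    val_part = (
        registry[plan.meta_domain].subset(meta_split.val_classes)
        if meta_split.val_classes else None
    )
    test_split = splits[plan.test_domain]
    test_part = registry[plan.test_domain].subset(test_split.test_classes)

    std = Standardizer.fit(base_part)
    encoder = Encoder(encoder_config, seed=encoder_seed)
    encoder, _head, base_hist = base_train(encoder, base_part, base_cfg, std)
    # the classifier head is discarded; meta-learning re-uses the encoder
    mhead = MetricHead(metric_config)
    encoder, meta_hist = meta_train(
        encoder, mhead, meta_part, meta_cfg, std, val_part
    )
    report = evaluate(
        encoder, test_part, eval_spec, eval_tasks, metric_config, eval_seed,
        std, split=test_split,
    )
    cfg_blob = json.dumps(
        {"encoder": asdict(encoder_config), "base": _cfg_dict(base_cfg),
         "meta": _cfg_dict(meta_cfg), "metric": asdict(metric_config)},
        sort_keys=True,
    )
    report.provenance.update({
        "plan": asdict(plan),
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest()[:12],
        "seeds": {"base": base_cfg.seed, "meta": meta_cfg.seed,
                  "eval": eval_seed, "encoder": encoder_seed},
        "base_history": base_hist,
        "meta_history": meta_hist,
        "wall_time_s": round(time.time() - t0, 2),
    })
    return encoder, report


def _cfg_dict(cfg: StageConfig) -> dict:
    d = asdict(cfg)
    if d.get("episode") is not None:
        d["episode"] = asdict(cfg.episode)
    return d
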