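import numpy as np
import pytest

import leafshot as ls
from leafshot.episodes import EpisodeSpec, make_splits
from leafshot.metric import MetricConfig, MetricHead
from leafshot.pipeline import (
    StageConfig, Standardizer, base_train, evaluate, meta_train, validate,
)


@pytest.fixture(scope="session")
def tiny_bank():
    """Six well-separated classes, 20 images each, 32x32."""
    return ls.generate_bank(6, 20, 2.0, ls.DomainSpec(image_size=32), seed=7)


@pytest.fixture(scope="session")
def flat_bank():
    """delta=0: every class shares the same appearance distribution."""
    return ls.generate_bank(5, 40, 0.0, ls.DomainSpec(image_size=32), seed=3)


@pytest.fixture(scope="session")
def small_encoder():
    return ls.Encoder(
        ls.EncoderConfig(base_width=4, fusion="cascaded", attention="channel"),
        seed=0,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """One scaled-down target-domain-only (S3) run shared by the slow tests.

    22 well-separated synthetic classes (100 images each, 32x32) split
    12 train / 4 val / 6 test; Conv4 encoder, cosine metric; short base
    and meta stages. Returns everything the trend/recovery checks need.
    """
    bank = ls.generate_bank(22, 100, 2.0, ls.DomainSpec(image_size=32), seed=11)
    split = make_splits(bank.class_ids, (12, 4, 6), seed=1)
    train = bank.subset(split.train_classes)
    val = bank.subset(split.val_classes)
    test = bank.subset(split.test_classes)
    std = Standardizer.fit(train)
    metric = MetricConfig("cosine", 10.0)
    enc = ls.Encoder(ls.EncoderConfig(base_width=16), seed=0)

    enc, _head, base_hist = base_train(
        enc, train,
        StageConfig("base", epochs=6, learning_rate=0.05, batch=64, seed=0),
        std,
    )
    pre_meta = evaluate(
        enc, test, EpisodeSpec(5, 5, 15), 200, metric, seed=5,
        standardizer=std, split=split,
    )
    mhead = MetricHead(metric)
    meta_cfg = StageConfig("meta", epochs=6, learning_rate=0.001, batch=4,
                           episode=EpisodeSpec(5, 1, 15), batches_per_epoch=15,
                           val_episodes=40, seed=0)
    # validation accuracy of the base-trained encoder on the exact episode
    # bank meta-training validates with (paired comparison)
    pre_meta_val = validate(
        enc, mhead, val, EpisodeSpec(min(5, len(val.class_ids)), 1, 15),
        meta_cfg.val_episodes, meta_cfg.seed, std,
    )
    enc, meta_hist = meta_train(enc, mhead, train, meta_cfg, std, val)
    post_meta = evaluate(
        enc, test, EpisodeSpec(5, 5, 15), 200, metric, seed=5,
        standardizer=std, split=split,
    )
    return {
        "bank": bank, "split": split, "test": test, "std": std,
        "encoder": enc, "metric": metric,
        "base_history": base_hist, "meta_history": meta_hist,
        "pre_meta": pre_meta, "post_meta": post_meta,
        "pre_meta_val": pre_meta_val,
        "bank_seed": 11, "delta": 2.0,
    }
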