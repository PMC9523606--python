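# leafshot

Few-shot recognition of plant diseases from leaf images, for researchers
who have many labelled images of *some* diseases but only a handful of the
diseases they actually need to recognise — the common situation when a new
pathogen appears or when field imagery differs from the lab imagery a model
was trained on.

## The method

`leafshot` implements a two-stage metric-learning pipeline over one shared
embedding network f<sub>θ</sub>:

1. **Base-training** — conventional supervised training of the encoder with
   a throwaway linear classifier on the training classes C_train.
2. **Meta-learning** — the classifier is removed and data is reformatted
   into *N-way K-shot* tasks: N classes, K labelled support images and W
   query images per class. Each class is represented by the centroid of its
   support embeddings

   ω_c = (1/|S_c|) Σ_{x_s∈S_c} f_θ(x_s)

   and a query x_q is classified by a scaled-similarity softmax

   p(y=c|x_q) = exp(γ·⟨f_θ(x_q), ω_c⟩) / Σ_{c′} exp(γ·⟨f_θ(x_q), ω_{c′}⟩)

   with a learnable temperature γ and ⟨·,·⟩ one of cosine similarity, dot
   product or negative Euclidean distance. Test classes C_novel never
   intersect the training classes.

The encoder is a four-block backbone (Conv4 or ResNet-12) whose per-block
feature taps are fused by **cascaded multi-scale feature fusion** (deep→
shallow upsample-and-concatenate, accumulating 15×`base_width` channels)
and reweighted by **channel attention** (average- and max-pooled channel
descriptors through a shared one-hidden-layer MLP, summed, sigmoid-gated).
Five **training strategies** S1–S5 assign a general (G), similar (S) or
target (T) domain to each of the three stages, e.g. S3 = (T,T,T) is pure
intra-domain, S4 = (G,S,T) is cross-domain transfer.

A built-in synthetic leaf-image generator (parametric leaf hue, lesion
frequency/density, one separability knob δ, and a domain model for
background/illumination/blur/noise) makes every stage runnable and testable
on one CPU without downloading any dataset; any per-class-directory image
folder (e.g. PlantVillage-style datasets) drops in through the same reader.
The package carries its own numpy reverse-mode autodiff engine, so it has
no GPU-framework dependency.

## Worked example

```python
import leafshot as ls
from leafshot.episodes import EpisodeSpec, make_splits
from leafshot.metric import MetricConfig, MetricHead
from leafshot.pipeline import (StageConfig, Standardizer,
                               base_train, meta_train, evaluate)

# 22 synthetic classes, 100 images each, split 12 train / 4 val / 6 test
from leafshot.pipeline import validate

bank = ls.generate_bank(22, 100, delta=2.0,
                        domain=ls.DomainSpec(image_size=32), seed=11)
split = make_splits(bank.class_ids, (12, 4, 6), seed=1)
train, val, test = (bank.subset(s) for s in
                    (split.train_classes, split.val_classes, split.test_classes))

std = Standardizer.fit(train)
metric = MetricConfig("cosine", gamma=10.0)
enc = ls.Encoder(ls.EncoderConfig(backbone="conv4", base_width=16), seed=0)

enc, _, _ = base_train(enc, train,
    StageConfig("base", epochs=6, learning_rate=0.05, batch=64, seed=0), std)

head = MetricHead(metric)
pre_val = validate(enc, head, val, EpisodeSpec(4, 1, 15), 40, 0, std)
enc, hist = meta_train(enc, head, train,
    StageConfig("meta", epochs=6, learning_rate=0.001, batch=4,
                episode=EpisodeSpec(5, 1, 15), batches_per_epoch=15,
                val_episodes=40, seed=0), std, val)
rep = evaluate(enc, test, EpisodeSpec(5, 5, 15), 200, metric,
               seed=5, standardizer=std, split=split)
print(f"validation 1-shot: {pre_val:.4f} -> "
      f"{max(h['val_acc'] for h in hist):.4f}")
print(f"held-out 5-way 5-shot: {rep.mean_accuracy:.4f}"
      f" +/- {rep.ci95_half_width:.4f}")
```

Output:

```
validation 1-shot: 0.9854 -> 0.9938
held-out 5-way 5-shot: 0.9410 +/- 0.0044
```

Read: episodic meta-learning lifts the base-trained encoder's one-shot
validation-task accuracy (measured on the identical fixed validation
episodes), and the final model classifies six *never-seen* disease classes
at 94.1% (±0.4%, 95% CI) from five examples each over 200 tasks. Accuracy
then rises with more shots and falls with more ways (`way_shot_sweep`).

The same flow is available from the shell (`leafshot genbank / split /
base-train / meta-train / eval / sweep / strategy`), driven by one YAML
config; see `leafshot --help`.

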