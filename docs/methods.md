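# Methods

## The model

`leafshot` implements metric-based few-shot classification for plant-disease
imagery in two training stages over one shared embedding network
f<sub>θ</sub>.

**Stage 1 — base-training.** The encoder plus a throwaway linear head is
trained by cross-entropy on image-wise batches over the training classes
C_train, exactly as a conventional classifier. The head is then discarded.

**Stage 2 — meta-learning.** Data is reformatted into N-way K-shot tasks:
each task draws N classes without replacement, then K support and W query
images per class (also without replacement, so support and query can never
share an image). Each class c is represented by the centroid of its support
embeddings,

    ω_c = (1/|S_c|) Σ_{x∈S_c} f_θ(x),

and a query x_q is classified through a scaled-similarity softmax,

    p(y=c | x_q) = exp(γ·⟨f_θ(x_q), ω_c⟩) / Σ_c' exp(γ·⟨f_θ(x_q), ω_c'⟩),

with ⟨·,·⟩ one of cosine similarity, dot product, or *negative* Euclidean
distance (the sign makes "closer" mean "larger" under the softmax; the
literature's "distance" is ambiguous on this point and a convention is
required). γ is a learnable temperature initialised at 10, the conventional
scaled-cosine choice; it lives only in the meta-learning head and is not
re-used from base-training. Training minimises the mean query cross-entropy;
evaluation samples many tasks from the held-out novel classes C_novel
(disjoint from C_train by construction, enforced by a contamination guard)
and reports the mean accuracy with a normal-approximation 95% CI.

## Encoder

Both backbones (Conv4 and ResNet-12) stack four blocks that double channels
and ceil-halve resolution, giving taps of shape (C, 2C, 4C, 8C) with
C = `base_width` (default 64; the desk-scale runs below use 16).

**Cascaded multi-scale fusion (CMSFF)** walks deep→shallow: the running map
is 2× nearest-neighbour upsampled, center-cropped/zero-padded to the next
tap's spatial size, and concatenated, accumulating 8C → 12C → 14C → 15C
channels at the shallowest resolution. The parallel variant (PMSFF)
upsamples every tap straight to the shallowest size and concatenates once;
with power-of-two inputs the two produce identical channel contents.
Nearest-neighbour upsampling was chosen because it is the cheapest scheme
that propagates constants exactly, which makes the fusion unit-testable;
the crop/pad rule handles odd (ceil-halved) sizes. No channel-reducing
convolution follows the concatenation by default — the raw fused map feeds
attention so that each channel remains an interpretable feature detector —
but a 1×1 reduction conv is available via `EncoderConfig.reduce_conv`.

**Channel attention** is the channel branch of CBAM: spatial average- and
max-pooling produce two C_F-vectors, both pass through one *shared*
one-hidden-layer MLP (hidden size max(C_F/r, 1), r = 16, ReLU), their sum
passes a sigmoid, and the resulting per-channel weights in (0,1) rescale
the fused map. The embedding is the global average pool of the attended
map, length 15·`base_width` (8·`base_width` when fusion is off). The three
ablation arms — plain backbone, +fusion, +fusion+attention — differ only in
config flags and share all other code paths.

Batch-norm statistics stay trainable during meta-learning (the simplest
defensible choice; freezing them is a known alternative). Base-training
uses the full configured encoder (fusion and attention included), so both
stages optimise the same architecture.

## Training strategies

A registry maps domain names to datasets; roles G (general), S (similar)
and T (target) realise the five transfer strategies as
(base, meta, test) triples: S1=(G,G,T), S2=(G,T,T), S3=(T,T,T),
S4=(G,S,T), S5=(S,S,T). S2/S3 are intra-domain, S1/S4/S5 cross-domain.

The optimiser is SGD with momentum 0.9 and weight decay 5·10⁻⁴ — the
standard recipe for these backbones; the sources of the published learning
rates never name the optimiser family, so this is a declared convention.
Model selection keeps the checkpoint with the best validation episode
accuracy, validated each epoch on freshly sampled fixed-seed episodes
(5-way 1-shot 15-query, way capped at the validation part's class count).
Fixed epoch counts plus best-validation checkpointing replace any
convergence-based stopping rule.

## Synthetic data generator

The generator emulates the *regimes* of leaf-disease benchmarks, not their
pixel statistics. Each class is a point in a 3-parameter appearance space —
leaf hue, lesion spatial frequency, lesion density — displaced from a
shared center (green leaf, mid-frequency sparse lesions) by a class-specific
random offset scaled by a single separability knob δ. δ = 0 collapses all
classes onto one distribution (a provable chance-level control); large δ
yields visually distinct classes; intermediate δ with nearby hues mimics
the sub-class regime where diseases of one crop look alike. An image is a
jittered ellipse ("leaf") of the class hue on a uniform neutral background,
with lesions cut from thresholded band-pass noise at the class's frequency
and density. Per-sample jitter (position, rotation, axes, mild hue/density
noise) comes from a stream seeded by (seed, class_id, sample_index), so
banks are bitwise reproducible and class streams never mix.

A domain is (background colour, illumination gain, blur radius, noise SD,
image size); the identity domain is a neutral mid-grey background with gain
1 and no blur/noise. `apply_domain_shift` transforms finished images in a
fixed order — background replacement, gain, blur, noise, clip to [0,1] —
emulating the lab-vs-field gap. Background replacement matches pixels
exactly equal to the neutral background, which is exact for banks rendered
in the identity domain; it is documented as a no-op otherwise. The shift
takes an explicit seed so the noise step stays reproducible.

What the generator does *not* emulate: real lesion morphology, leaf venation
and shape diversity, multiple leaves or diseases per image, class imbalance,
and label noise. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its comparative directions (meta-learning
lift, shot/way trends, fusion/attention ordering) emerge under controlled
conditions — not that any particular accuracy transfers to field imagery.

## Numerical core

No GPU tensor framework is a dependency: the package carries its own
reverse-mode autodiff engine on float32 numpy arrays (`leafshot.autodiff`)
with exactly the operator set the encoder needs — im2col convolution,
ceil-mode 2×2 max-pooling, nearest 2× upsampling, crop/pad, batch norm,
and the usual elementwise/reduction ops. Every primitive is verified
against central finite differences in the test suite. Determinism holds
single-threaded for a fixed seed; all random streams (weight init, batch
order, episode sampling, generator) are numpy `default_rng` substreams
keyed by explicit seeds.

Ties in argmax predictions break toward the lowest class index. Cosine
similarity raises on (near-)zero vectors instead of returning NaN. The
Euclidean similarity adds 1e-12 inside the square root during training to
keep the gradient finite at zero distance.

## Desk-scale study conditions

The self-contained runs used by the tests and the acceptance script:

- **Recovery run (S3):** 22 classes × 100 images, 32×32, δ = 2.0, split
  12 train / 4 val / 6 test; Conv4 with base width 16, cosine metric,
  γ = 10; base-training 6 epochs (lr 0.05, batch 64), meta-learning
  6 epochs × 15 task-batches of 4 five-way one-shot tasks (lr 0.001),
  40 validation episodes per epoch; evaluation 200 five-way five-shot
  episodes. These sizes are the package's chosen desk-scale conditions —
  large enough for stable estimates, small enough to run on one CPU core
  in a few minutes. The meta-learning stage's contribution is measured
  the way the lifting ranges are conventionally reported for this
  two-stage design: pre- vs post-meta accuracy on the *identical*
  fixed-seed validation episode bank (a paired comparison). Held-out
  *test* accuracy is near its ceiling on this synthetic family after
  base-training alone, so the test-side delta is reported but is not the
  lift measurement; on real, harder data the validation-side lift is the
  quantity that tracks the meta stage's value.
- **Chance control:** untrained encoder, δ = 0 bank (8 classes × 40),
  500 five-way one-shot episodes.
- **Way sweep:** the 8-way cell needs more novel classes than the 6-class
  test part offers, so the way sweep evaluates on a freshly generated
  8-class bank from the same generator distribution (unseen class ids,
  same δ and domain) — the same "novel classes" condition.
- **Ablation:** 5 seeds × 3 arms on a cross-domain setup (base-training on
  a general identity-domain bank; meta-learning and test on a shifted
  target bank: tinted background, gain 1.3, blur 0.6 px, noise 0.03),
  16×16 images, base width 8, short schedules; the comparison is reported
  with CIs and soft-gated at one standard error per adjacent pair.

## Known limitations

- The autodiff engine is single-threaded numpy; it is meant for desk-scale
  experiments and correctness, not for GPU-scale benchmark reproduction.
- Backbones beyond Conv4/ResNet-12 must be plugged in by the user; spatial
  attention is deliberately out of scope (only the channel branch is used).
- The synthetic domain gap is low-dimensional; conclusions about *which*
  transfer strategy wins on real lab-vs-field data require real data, which
  the image-folder reader accepts as a drop-in replacement for banks.
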