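"""Prototype/metric head against straight-from-the-formula oracles."""

import numpy as np
import pytest

from leafshot.autodiff import Tensor
from leafshot.metric import (
    MetricConfig, MetricHead, class_centroid, cross_entropy,
    episode_accuracy, episode_logits, episode_loss, pairwise_similarity,
    similarity,
)

COS = MetricConfig("cosine", 1.0)
DOT = MetricConfig("dot", 1.0)
EUC = MetricConfig("euclidean", 1.0)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TestCentroid:
    def test_arithmetic_mean(self):
        assert np.allclose(class_centroid([(1, 2), (3, 4)]), (2, 3))

    def test_single_shot_identity_and_permutation_symmetry(self):
        v = np.array([0.3, -1.2, 5.0])
        assert np.array_equal(class_centroid([v]), v)
        vs = [np.array([1.0, 0]), np.array([0, 1.0]), np.array([2.0, 2.0])]
        assert np.allclose(class_centroid(vs), class_centroid(vs[::-1]))

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            class_centroid([])
        with pytest.raises(ValueError):
            class_centroid([np.zeros(2), np.zeros(3)])


class TestSimilarity:
    def test_cosine_orthogonal_parallel_scale_invariant(self):
        assert similarity((1, 0), (0, 1), COS) == pytest.approx(0.0)
        assert similarity((1, 1), (1, 1), COS) == pytest.approx(1.0)
        assert similarity((1, 1), (2, 2), COS) == pytest.approx(1.0)

    def test_euclidean_three_four_five(self):
        assert similarity((0, 0), (3, 4), EUC) == pytest.approx(-5.0)

    def test_dot_product(self):
        assert similarity((1, 2), (3, 4), DOT) == pytest.approx(11.0)

    def test_cosine_zero_vector_guard(self):
        with pytest.raises(ValueError, match="zero"):
            similarity((0, 0), (1, 1), COS)


class TestLogits:
    def test_equidistant_prototypes_uniform_probabilities(self):
        protos = np.array([[1.0, 0], [0, 1.0]])
        q = np.array([[1.0, 1.0]])
        for cfg in (MetricConfig("cosine", 7.0), MetricConfig("euclidean", 3.0)):
            p = softmax(episode_logits(q, protos, cfg))
            assert np.allclose(p, 0.5)

    def test_cosine_two_way_softmax_value(self):
        # sims (1, 0) at gamma=1 -> p = (e/(e+1), 1/(e+1))
        protos = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = np.array([[1.0, 0.0]])
        p = softmax(episode_logits(q, protos, MetricConfig("cosine", 1.0)))
        e = np.e
        assert np.allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-9)

    def test_gamma_zero_degenerate_uniform(self):
        rng = np.random.default_rng(0)
        q, protos = rng.normal(size=(4, 6)), rng.normal(size=(3, 6))
        p = softmax(episode_logits(q, protos, MetricConfig("dot", 0.0)))
        assert np.allclose(p, 1 / 3)

    def test_rows_sum_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(10, 5))
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(softmax(logits + 3.7), p, atol=1e-9)

    def test_cosine_logits_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(2)
        q, protos = rng.normal(size=(4, 8)), rng.normal(size=(3, 8))
        a = episode_logits(q, protos, MetricConfig("cosine", 5.0))
        b = episode_logits(2.5 * q, 0.3 * protos, MetricConfig("cosine", 5.0))
        assert np.allclose(a, b, atol=1e-9)


class TestLossAccuracy:
    def test_uniform_logits_loss_is_ln_n(self):
        for n in (2, 5, 7):
            loss = episode_loss(np.zeros((6, n)), np.arange(6) % n)
            assert loss == pytest.approx(np.log(n), abs=1e-9)

    def test_confident_correct_logits_drive_loss_to_zero(self):
        logits = np.full((4, 3), -50.0)
        labels = np.array([0, 1, 2, 0])
        logits[np.arange(4), labels] = 50.0
        assert episode_loss(logits, labels) < 1e-9
        assert episode_accuracy(logits, labels) == 1.0

    def test_loss_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(20, 5))
        labels = rng.integers(0, 5, 20)
        p = softmax(logits)
        oracle = -np.mean(np.log(p[np.arange(20), labels]))
        assert episode_loss(logits, labels) == pytest.approx(oracle, abs=1e-6)
        t_loss = episode_loss(Tensor(logits.astype(np.float32)), labels)
        assert float(t_loss.data) == pytest.approx(oracle, abs=1e-5)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            episode_loss(np.zeros((2, 3)), [0, 3])
        with pytest.raises(ValueError):
            episode_accuracy(np.zeros((2, 3)), [-1, 0])

    def test_tie_break_predicts_lowest_index(self):
        logits = np.zeros((5, 4))
        assert episode_accuracy(logits, np.zeros(5, dtype=int)) == 1.0
        assert episode_accuracy(logits, np.ones(5, dtype=int)) == 0.0

    def test_shuffled_labels_accuracy_equals_brute_count(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(30, 2))
        labels = rng.integers(0, 2, 30)
        brute = sum(
            int(np.argmax(row) == lab) for row, lab in zip(logits, labels)
        ) / 30
        assert episode_accuracy(logits, labels) == pytest.approx(brute)


class TestPipelineOracles:
    def test_centroid_softmax_pipeline_matches_formula_oracle(self):
        """Random small episodes through centroid + scaled softmax must match
        an independent straight-from-the-definitions recomputation."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n, k, w, d = rng.integers(2, 7), rng.integers(1, 4), 3, 8
            sup = rng.normal(size=(n, k, d))
            qry = rng.normal(size=(n * w, d))
            gamma = float(rng.uniform(0.5, 20))
            for metric in ("cosine", "dot", "euclidean"):
                cfg = MetricConfig(metric, gamma)
                protos = np.stack([class_centroid(sup[c]) for c in range(n)])
                logits = episode_logits(qry, protos, cfg)
                # oracle: scalar loops, no shared code with the implementation
                oracle = np.empty((n * w, n))
                for qi in range(n * w):
                    for c in range(n):
                        mu = sup[c].mean(axis=0)
                        if metric == "cosine":
                            s = qry[qi] @ mu / (
                                np.linalg.norm(qry[qi]) * np.linalg.norm(mu)
                            )
                        elif metric == "dot":
                            s = qry[qi] @ mu
                        else:
                            s = -np.linalg.norm(qry[qi] - mu)
                        oracle[qi, c] = gamma * s
                assert np.abs(logits - oracle).max() < 1e-6

    def test_one_shot_euclidean_equals_nearest_neighbour(self):
        """K=1 nearest-centroid with euclidean metric is exactly 1-NN."""
        rng = np.random.default_rng(6)
        for _ in range(200):
            n, d, w = int(rng.integers(2, 7)), int(rng.integers(2, 17)), 5
            protos = rng.normal(size=(n, d))
            qry = rng.normal(size=(w, d))
            logits = episode_logits(qry, protos, MetricConfig("euclidean", 1.0))
            pred = np.argmax(logits, axis=1)
            nn = np.array([
                np.argmin([np.linalg.norm(q - p) for p in protos]) for q in qry
            ])
            assert np.array_equal(pred, nn)


def test_export_logits_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    logits = rng.normal(size=(6, 3))
    labels = rng.integers(0, 3, 6)
    path = tmp_path / "logits.tsv"
    from leafshot.metric import export_logits
    export_logits(logits, labels, str(path))
    back = np.loadtxt(path, delimiter="\t")
    assert np.allclose(back[:, 0], labels)
    assert np.allclose(back[:, 1:], logits)


def test_metric_head_trains_gamma():
    head = MetricHead(MetricConfig("cosine", 10.0, trainable_gamma=True))
    assert head.gamma.requires_grad
    q = Tensor(np.random.default_rng(7).normal(size=(4, 3)).astype(np.float32))
    p = Tensor(np.random.default_rng(8).normal(size=(2, 3)).astype(np.float32))
    logits = head.logits(q, p)
    loss = cross_entropy(logits, np.array([0, 1, 0, 1]))
    loss.backward()
    assert head.gamma.grad is not None and np.isfinite(head.gamma.grad).all()
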