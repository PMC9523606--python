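"""Nearest-centroid metric head: prototypes, similarities, scaled-softmax
classification, episode loss and accuracy.

A class prototype is the centroid (arithmetic mean) of its support
embeddings,

    omega_c = (1/|S_c|) * sum_{x in S_c} f_theta(x),

and a query is classified by the softmax over its scaled similarities to
the prototypes,

    p(y=c | x_q) = exp(gamma * <f(x_q), omega_c>) / sum_c' exp(gamma * <f(x_q), omega_c'>),

where gamma is a learnable temperature and <.,.> is one of cosine
similarity, dot product, or negative Euclidean distance (the sign makes
"closer" mean "larger" inside the softmax). Training minimises the mean
cross-entropy of the queries' episode labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, Module, Parameter

__all__ = [
    "MetricConfig",
    "MetricHead",
    "class_centroid",
    "similarity",
    "pairwise_similarity",
    "episode_logits",
    "episode_loss",
    "episode_accuracy",
    "cross_entropy",
    "export_logits",
]

METRICS = ("cosine", "dot", "euclidean")
_EPS = 1e-12


@dataclass(frozen=True)
class MetricConfig:
    """Distance metric and softmax temperature settings."""

    metric: str = "cosine"
    gamma: float = 10.0      # conventional scaled-cosine initialisation
    trainable_gamma: bool = True

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")


def class_centroid(embeddings) -> np.ndarray:
    """Arithmetic-mean prototype of a nonempty list of equal-length vectors."""
    vecs = [np.asarray(v, dtype=np.float64) for v in embeddings]
    if not vecs:
        raise ValueError("cannot take the centroid of an empty support set")
    dims = {v.shape for v in vecs}
    if len(dims) != 1 or vecs[0].ndim != 1:
        raise ValueError(f"embedding dimensions disagree: {dims}")
    return np.mean(vecs, axis=0)


def similarity(u, v, config: MetricConfig) -> float:
    """Similarity of two vectors under the configured metric (scalar)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length vectors")
    if config.metric == "dot":
        return float(u @ v)
    if config.metric == "euclidean":
        return float(-np.sqrt(np.sum((u - v) ** 2)))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float((u @ v) / (nu * nv))


def _pairwise_np(q: np.ndarray, p: np.ndarray, metric: str) -> np.ndarray:
    if metric == "dot":
        return q @ p.T
    if metric == "euclidean":
        d2 = (
            np.sum(q ** 2, axis=1, keepdims=True)
            - 2.0 * q @ p.T
            + np.sum(p ** 2, axis=1)
        )
        return -np.sqrt(np.maximum(d2, 0.0))
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    pn = np.linalg.norm(p, axis=1, keepdims=True)
    if np.any(qn < _EPS) or np.any(pn < _EPS):
        raise ValueError("cosine similarity is undefined for a zero vector")
    return (q / qn) @ (p / pn).T


def _pairwise_ad(q: Tensor, p: Tensor, metric: str) -> Tensor:
    if metric == "dot":
        return q @ p.transpose()
    if metric == "euclidean":
        q2 = (q * q).sum(axis=1, keepdims=True)
        p2 = (p * p).sum(axis=1, keepdims=True)
        d2 = q2 - 2.0 * (q @ p.transpose()) + p2.transpose()
        return -(d2.relu() + _EPS).sqrt()
    qn = ((q * q).sum(axis=1, keepdims=True) + _EPS).sqrt()
    pn = ((p * p).sum(axis=1, keepdims=True) + _EPS).sqrt()
    if np.any(qn.data < 1e-6) or np.any(pn.data < 1e-6):
        raise ValueError("cosine similarity is undefined for a zero vector")
    return (q / qn) @ (p / pn).transpose()


def pairwise_similarity(queries, prototypes, config: MetricConfig):
    """(n_query, N) similarity matrix; Tensor in, Tensor out."""
    if isinstance(queries, Tensor) or isinstance(prototypes, Tensor):
        q = queries if isinstance(queries, Tensor) else Tensor(queries)
        p = prototypes if isinstance(prototypes, Tensor) else Tensor(prototypes)
        return _pairwise_ad(q, p, config.metric)
    return _pairwise_np(
        np.asarray(queries, dtype=np.float64),
        np.asarray(prototypes, dtype=np.float64),
        config.metric,
    )


def episode_logits(query_embeddings, prototypes, config: MetricConfig,
                   gamma=None):
    """Scaled similarity logits: logit(q, c) = gamma * sim(f(x_q), omega_c)."""
    sims = pairwise_similarity(query_embeddings, prototypes, config)
    g = config.gamma if gamma is None else gamma
    return sims * g


def cross_entropy(logits, labels) -> "Tensor | float":
    """Mean cross-entropy of softmax(logits) rows against integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    n_cls = logits.shape[1]
    if labels.min() < 0 or labels.max() >= n_cls:
        raise ValueError(f"labels must lie in 0..{n_cls - 1}")
    onehot = np.eye(n_cls, dtype=np.float32)[labels]
    if isinstance(logits, Tensor):
        z = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        lse = z.exp().sum(axis=1).log()
        picked = (z * Tensor(onehot)).sum(axis=1)
        return (lse - picked).mean()
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return float(np.mean(lse - z[np.arange(len(labels)), labels]))


def episode_loss(logits, labels):
    """Episode training loss (mean cross-entropy, >= 0)."""
    return cross_entropy(logits, labels)


def episode_accuracy(logits, labels) -> float:
    """Fraction of queries whose argmax logit matches the episode label.
    Ties break toward the lowest class index."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= arr.shape[1]:
        raise ValueError("label out of range")
    pred = np.argmax(arr, axis=1)  # numpy argmax takes the first maximum
    return float(np.mean(pred == labels))


def export_logits(logits, labels, path: str, delimiter: str = "\t") -> None:
    """Dump per-episode logits (plus the true episode label) as delimited
    text for debugging."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    labels = np.asarray(labels).reshape(-1, 1)
    np.savetxt(path, np.hstack([labels, arr]), delimiter=delimiter,
               header=delimiter.join(
                   ["label"] + [f"logit_{c}" for c in range(arr.shape[1])]
               ))


class MetricHead(Module):
    """Holds the (optionally trainable) temperature gamma for training."""

    def __init__(self, config: MetricConfig):
        super().__init__()
        self.config = config
        if config.trainable_gamma:
            self.gamma = Parameter(np.float32(config.gamma))
        else:
            self.gamma = Tensor(np.float32(config.gamma))

    def logits(self, query_embeddings: Tensor, prototypes: Tensor) -> Tensor:
        sims = pairwise_similarity(query_embeddings, prototypes, self.config)
        return sims * self.gamma

    @property
    def gamma_value(self) -> float:
        return float(self.gamma.data)
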