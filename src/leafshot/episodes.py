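"""Class splits, episodic N-way/K-shot task sampling, and training-strategy
resolution.

Few-shot evaluation requires that the class sets used for training,
validation and testing never intersect; `SplitSpec` enforces that. An
episode (task) is one self-contained N-way classification problem: N
classes drawn without replacement, K support and W query images per class,
with episode-local labels 0..N-1 assigned in class-draw order. The five
training strategies S1-S5 choose which domain (general G, similar S,
target T) feeds each of base-training, meta-learning and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import ImageBank

__all__ = [
    "SplitSpec",
    "EpisodeSpec",
    "EpisodeTask",
    "StagePlan",
    "SplitError",
    "SamplingError",
    "PlanError",
    "make_splits",
    "sample_episode",
    "batch_episodes",
    "resolve_strategy",
    "STRATEGY_TABLE",
]


class SplitError(ValueError):
    """Invalid class-split request (overlap, insufficient classes)."""


class SamplingError(ValueError):
    """Episode cannot be drawn from the given data part."""


class PlanError(ValueError):
    """A training strategy cannot be realised against the registry."""


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train / validation / test class sets."""

    train_classes: frozenset[int]
    val_classes: frozenset[int]
    test_classes: frozenset[int]

    def __post_init__(self):
        a, b, c = self.train_classes, self.val_classes, self.test_classes
        if a & b or a & c or b & c:
            raise SplitError("train/val/test class sets must be disjoint")

    def to_text(self) -> str:
        lines = []
        for name, ids in (("[train]", self.train_classes),
                          ("[val]", self.val_classes),
                          ("[test]", self.test_classes)):
            lines.append(name)
            lines.extend(str(c) for c in sorted(ids))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SplitSpec":
        parts: dict[str, set[int]] = {"[train]": set(), "[val]": set(), "[test]": set()}
        current = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line in parts:
                current = line
            elif current is None:
                raise SplitError(f"class id before section header: {line!r}")
            else:
                parts[current].add(int(line))
        return cls(frozenset(parts["[train]"]), frozenset(parts["[val]"]),
                   frozenset(parts["[test]"]))


@dataclass(frozen=True)
class EpisodeSpec:
    """N-way, K-shot, W-query episode geometry."""

    n_way: int
    k_shot: int
    w_query: int

    def __post_init__(self):
        if self.n_way < 2:
            raise SamplingError("n_way must be >= 2")
        if self.k_shot < 1 or self.w_query < 1:
            raise SamplingError("k_shot and w_query must be >= 1")


@dataclass
class EpisodeTask:
    """One few-shot task: support S, query Q, and the episode-label map."""

    support_images: np.ndarray   # (N*K, 3, H, W)
    support_labels: np.ndarray   # (N*K,) episode labels 0..N-1
    query_images: np.ndarray     # (N*W, 3, H, W)
    query_labels: np.ndarray     # (N*W,)
    class_map: dict[int, int]    # episode label -> original class id
    support_indices: np.ndarray = field(default=None, repr=False)
    query_indices: np.ndarray = field(default=None, repr=False)

    @property
    def n_way(self) -> int:
        return len(self.class_map)


def make_splits(class_ids, counts: tuple[int, int, int] | None = None,
                seed: int | None = None,
                explicit: tuple[set, set, set] | None = None) -> SplitSpec:
    """Partition a class registry into disjoint train/val/test sets.

    Either pass ``counts=(n_train, n_val, n_test)`` with a ``seed`` for a
    random partition, or ``explicit=(train, val, test)`` sets which are
    honoured verbatim (and checked for disjointness and membership).
    """
    ids = sorted(int(c) for c in class_ids)
    if explicit is not None:
        tr, va, te = (frozenset(int(c) for c in s) for s in explicit)
        unknown = (tr | va | te) - set(ids)
        if unknown:
            raise SplitError(f"unknown class ids in explicit split: {sorted(unknown)}")
        return SplitSpec(tr, va, te)
    if counts is None:
        raise SplitError("need counts or an explicit assignment")
    n_train, n_val, n_test = counts
    if min(counts) < 0 or n_train + n_val + n_test > len(ids):
        raise SplitError(
            f"counts {counts} infeasible for {len(ids)} classes"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    tr = frozenset(int(c) for c in perm[:n_train])
    va = frozenset(int(c) for c in perm[n_train:n_train + n_val])
    te = frozenset(int(c) for c in perm[n_train + n_val:n_train + n_val + n_test])
    return SplitSpec(tr, va, te)


def sample_episode(part: ImageBank, spec: EpisodeSpec,
                   rng: np.random.Generator) -> EpisodeTask:
    """Draw one N-way K-shot W-query episode from a data part.

    Classes are drawn uniformly without replacement; within each class,
    K+W samples are drawn without replacement, the first K forming the
    support set and the next W the query set, so the two sets can never
    share a sample. Episode labels follow class-draw order.
    """
    n, k, w = spec.n_way, spec.k_shot, spec.w_query
    by_class = part.indices_by_class()
    classes = list(by_class)
    if len(classes) < n:
        raise SamplingError(
            f"need {n} classes but the part has only {len(classes)}"
        )
    short = {c: len(ix) for c, ix in by_class.items() if len(ix) < k + w}
    if len(classes) - len(short) < n:
        raise SamplingError(
            f"not enough classes with >= {k + w} samples; deficits: {short}"
        )
    eligible = [c for c in classes if c not in short]
    drawn = rng.choice(len(eligible), size=n, replace=False)
    sup_im, sup_y, qry_im, qry_y = [], [], [], []
    sup_ix, qry_ix = [], []
    class_map: dict[int, int] = {}
    for ep_label, ci in enumerate(drawn):
        cid = eligible[int(ci)]
        class_map[ep_label] = cid
        pick = rng.choice(by_class[cid], size=k + w, replace=False)
        sup_ix.append(pick[:k])
        qry_ix.append(pick[k:])
        sup_im.append(part.images[pick[:k]])
        qry_im.append(part.images[pick[k:]])
        sup_y.extend([ep_label] * k)
        qry_y.extend([ep_label] * w)
    return EpisodeTask(
        np.concatenate(sup_im), np.asarray(sup_y, dtype=np.int64),
        np.concatenate(qry_im), np.asarray(qry_y, dtype=np.int64),
        class_map,
        support_indices=np.concatenate(sup_ix),
        query_indices=np.concatenate(qry_ix),
    )


def batch_episodes(part: ImageBank, spec: EpisodeSpec, tasks_per_batch: int,
                   rng: np.random.Generator) -> list[EpisodeTask]:
    """Sample ``tasks_per_batch`` independent episodes (one meta-batch)."""
    if tasks_per_batch < 1:
        raise SamplingError("tasks_per_batch must be >= 1")
    return [sample_episode(part, spec, rng) for _ in range(tasks_per_batch)]


# strategy -> (base-training domain role, meta-learning role, test role)
STRATEGY_TABLE: dict[str, tuple[str, str, str]] = {
    "S1": ("G", "G", "T"),
    "S2": ("G", "T", "T"),
    "S3": ("T", "T", "T"),
    "S4": ("G", "S", "T"),
    "S5": ("S", "S", "T"),
}


@dataclass(frozen=True)
class StagePlan:
    """One strategy realised as concrete domains for the three stages."""

    strategy_id: str
    base_domain: str
    meta_domain: str
    test_domain: str


def resolve_strategy(strategy_id: str, roles: dict[str, str],
                     registry: dict[str, ImageBank]) -> StagePlan:
    """Resolve S1..S5 to a StagePlan given role assignments.

    ``roles`` maps role letters {"G", "S", "T"} to registry domain names;
    only the roles a strategy uses need to be present.
    """
    if strategy_id not in STRATEGY_TABLE:
        raise PlanError(f"unknown strategy {strategy_id!r}")
    needed = STRATEGY_TABLE[strategy_id]
    doms = []
    for role in needed:
        if role not in roles:
            raise PlanError(f"strategy {strategy_id} needs role {role!r}")
        name = roles[role]
        if name not in registry:
            raise PlanError(f"domain {name!r} (role {role}) not in registry")
        doms.append(name)
    return StagePlan(strategy_id, *doms)
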