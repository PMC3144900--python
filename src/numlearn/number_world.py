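"""Synthetic number-learning environment.

Generates the learning events a child might face when hearing number words:
sets of 1-20 objects carrying *nested* numerosity cues (a set of n objects
activates the cues ``num1 .. num_n``, so larger sets contain the cues of every
smaller set) plus competing, unreliable color/shape/size cues; labels for the
set sizes; and training schedules whose set-size composition follows either
equal frequency or the inverse-power spoken-frequency distribution of number
words.

Temporal arrangements:

* FL (Feature-to-Label, postnominal phrasing): the object features are cues
  predicting the number label, which allows cue competition.
* LF (Label-to-Feature, prenominal phrasing): the label is the sole cue
  predicting the features, so no competition can occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .learning_core import Trial

__all__ = [
    "NUMBER_WORDS",
    "number_word",
    "size_labels",
    "FeaturePools",
    "ObjectSet",
    "CueCoding",
    "ScheduleSpec",
    "encode_set",
    "make_trial",
    "allocate_counts",
    "build_events",
    "build_schedule",
    "fl_block_246",
]

NUMBER_WORDS = (
    "one", "two", "three", "four", "five", "six", "seven", "eight", "nine",
    "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen", "sixteen",
    "seventeen", "eighteen", "nineteen", "twenty",
)

MAX_SET_SIZE = 20


def number_word(n: int) -> str:
    """English label for a set size 1-20."""
    if not 1 <= n <= MAX_SET_SIZE:
        raise ValueError(f"set size must be in 1..{MAX_SET_SIZE}, got {n}")
    return NUMBER_WORDS[n - 1]


def size_labels(sizes: Iterable[int]) -> dict[int, str]:
    """Mapping set size -> label for the given sizes."""
    return {n: number_word(n) for n in sizes}


@dataclass(frozen=True)
class FeaturePools:
    """Finite pools of feature values objects can take on each dimension."""

    colors: tuple[str, ...] = ("red", "blue", "green")
    shapes: tuple[str, ...] = ("round", "square", "star")
    sizes: tuple[str, ...] = ("small", "medium", "large")

    def __post_init__(self) -> None:
        if not (self.colors and self.shapes and self.sizes):
            raise ValueError("feature pools must be non-empty")


@dataclass(frozen=True)
class ObjectSet:
    """A set of identical objects: a count plus feature values."""

    set_size: int
    color: str | None = None
    shape: str | None = None
    size_feat: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.set_size <= MAX_SET_SIZE:
            raise ValueError(
                f"set_size must be in 1..{MAX_SET_SIZE}, got {self.set_size}"
            )


@dataclass(frozen=True)
class CueCoding:
    """How an object set is translated into cue identifiers.

    The numerosity scheme is nested: a set of size n activates ``num1..num_n``,
    so the cues of a size-n set are a strict subset of those of a size-(n+1)
    set.  This containment is what makes larger sets progressively more
    confusable.  ``include_features`` adds one cue per feature dimension
    (``color:red`` etc.) as competitors.
    """

    include_features: bool = True
    numerosity_prefix: str = "num"

    def numerosity_cues(self, n: int) -> frozenset[str]:
        if not 1 <= n <= MAX_SET_SIZE:
            raise ValueError(f"set size must be in 1..{MAX_SET_SIZE}, got {n}")
        return frozenset(f"{self.numerosity_prefix}{i}" for i in range(1, n + 1))


def encode_set(s: ObjectSet, coding: CueCoding) -> frozenset[str]:
    """Cue identifiers active when looking at object set ``s``."""
    cues = set(coding.numerosity_cues(s.set_size))
    if coding.include_features:
        if s.color is not None:
            cues.add(f"color:{s.color}")
        if s.shape is not None:
            cues.add(f"shape:{s.shape}")
        if s.size_feat is not None:
            cues.add(f"size:{s.size_feat}")
    return frozenset(cues)


def make_trial(s: ObjectSet, label: str, arrangement: str, coding: CueCoding) -> Trial:
    """One learning event under the given temporal arrangement.

    FL: features are cues, the label is the outcome.  LF: the label is the
    sole cue, the features are outcomes.  The two are exact mirrors of the
    same world event.
    """
    arr = arrangement.upper()
    features = encode_set(s, coding)
    if arr == "FL":
        return Trial(cues=features, outcomes={label})
    if arr == "LF":
        return Trial(cues={label}, outcomes=features)
    raise ValueError(f"unknown arrangement {arrangement!r}; expected 'FL' or 'LF'")


@dataclass(frozen=True)
class ScheduleSpec:
    """Set-size composition of a training sequence.

    modes
    -----
    equal : each size appears n_trials / len(sizes) times (any remainder is
        given to the smallest sizes first); trial order seeded-shuffled.
    weighted-deterministic : per-size counts are the largest-remainder
        rounding of n_trials * weight / sum(weights); order seeded-shuffled.
    weighted-sampled : sizes drawn i.i.d. with probability proportional to
        the weights under the seed.
    """

    sizes: tuple[int, ...]
    n_trials: int
    weights: tuple[float, ...] | None = None
    mode: str = "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(set(self.sizes)) != len(self.sizes) or not self.sizes:
            raise ValueError("sizes must be a non-empty list of distinct set sizes")
        if self.mode not in ("equal", "weighted-sampled", "weighted-deterministic"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode != "equal":
            if self.weights is None or len(self.weights) != len(self.sizes):
                raise ValueError("weighted modes need one weight per size")
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be non-negative with a positive sum")


def allocate_counts(weights: Sequence[float], n_trials: int) -> list[int]:
    """Largest-remainder apportionment of n_trials to the given weights."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    quota = n_trials * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_trials - counts.sum()
    # ties broken toward earlier (smaller) sizes for determinism
    for i in sorted(range(len(w)), key=lambda i: (-remainder[i], i))[:short]:
        counts[i] += 1
    return counts.tolist()


def _size_sequence(spec: ScheduleSpec, rng: np.random.Generator) -> list[int]:
    if spec.mode == "weighted-sampled":
        p = np.asarray(spec.weights, dtype=float)
        return list(rng.choice(spec.sizes, size=spec.n_trials, p=p / p.sum()))
    if spec.mode == "equal":
        counts = allocate_counts([1.0] * len(spec.sizes), spec.n_trials)
    else:
        counts = allocate_counts(spec.weights, spec.n_trials)
    seq = [s for s, c in zip(spec.sizes, counts) for _ in range(c)]
    rng.shuffle(seq)
    return seq


def _rotated_features(pools: FeaturePools, k: int) -> tuple[str, str, str]:
    # Latin-square-style rotation: the shape and size cycles shift phase on
    # every completed color cycle, so any run of occurrences spreads feature
    # values as evenly as divisibility allows and no value tracks a label.
    nc, ns, nz = len(pools.colors), len(pools.shapes), len(pools.sizes)
    return (
        pools.colors[k % nc],
        pools.shapes[(k + k // nc) % ns],
        pools.sizes[(k + k // (nc * ns)) % nz],
    )


def build_events(
    spec: ScheduleSpec,
    pools: FeaturePools = FeaturePools(),
    coding: CueCoding = CueCoding(),
) -> list[tuple[ObjectSet, str]]:
    """Ordered (object set, label) events realizing the schedule.

    Feature values rotate per label so that over the schedule every feature
    value co-occurs with every in-scope label as evenly as divisibility
    allows — features must not be reliable predictors of any one label.
    Labels always match the set size here; mislabelled events can be built
    directly with :func:`make_trial`.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _size_sequence(spec, rng)
    seen: dict[int, int] = {}
    events = []
    for n in sizes:
        k = seen.get(n, 0)
        seen[n] = k + 1
        if coding.include_features:
            color, shape, size_feat = _rotated_features(pools, k)
            obj = ObjectSet(n, color=color, shape=shape, size_feat=size_feat)
        else:
            obj = ObjectSet(n)
        events.append((obj, number_word(n)))
    return events


def build_schedule(
    spec: ScheduleSpec,
    pools: FeaturePools = FeaturePools(),
    coding: CueCoding = CueCoding(),
    arrangement: str = "FL",
) -> list[Trial]:
    """Trial stream for the schedule under one temporal arrangement."""
    return [
        make_trial(obj, label, arrangement, coding)
        for obj, label in build_events(spec, pools, coding)
    ]


def fl_block_246(
    n_blocks: int,
    pools: FeaturePools = FeaturePools(),
    coding: CueCoding = CueCoding(),
) -> list[Trial]:
    """FL training blocks of 2, then 4, then 6 objects of one item kind.

    Each block presents sets of 2, 4 and 6 objects in ascending order, all
    sharing one feature bundle (the "item"), with a distinct bundle per
    block; 6 blocks give 18 trials.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    trials = []
    for b in range(n_blocks):
        nc, ns = len(pools.colors), len(pools.shapes)
        color = pools.colors[b % nc]
        shape = pools.shapes[(b // nc) % ns]
        size_feat = pools.sizes[(b // (nc * ns)) % len(pools.sizes)]
        for n in (2, 4, 6):
            obj = ObjectSet(n, color=color, shape=shape, size_feat=size_feat)
            trials.append(make_trial(obj, number_word(n), "FL", coding))
    return trials
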