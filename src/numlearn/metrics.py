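"""Read-outs of the learned association matrix.

Activation of a label by a stimulus is the plain sum of the weights of the
cues present — the learner's total prediction of that label.  On top of this
the module provides a per-set-size discrimination score and a
three-alternative forced-choice decision rule mirroring a behavioral test
(three candidate arrays, one requested label; chance accuracy 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .learning_core import AssociationMatrix
from .number_world import CueCoding, ObjectSet, encode_set

__all__ = [
    "ActivationProfile",
    "activate",
    "discrimination_score",
    "forced_choice",
    "forced_choice_accuracy",
]


@dataclass(frozen=True)
class ActivationProfile:
    """Summed associative value of every outcome for one stimulus."""

    cues: frozenset[str]
    activations: dict[str, float]

    def __getitem__(self, outcome: str) -> float:
        return self.activations.get(outcome, 0.0)


def activate(V: AssociationMatrix, cues: Sequence[str] | frozenset[str]) -> ActivationProfile:
    """Linear activation: for each outcome, the sum of V over present cues."""
    if not V.is_finite():
        raise ValueError("association matrix contains NaN or infinite values")
    cueset = frozenset(cues)
    acts = {o: V.summed_prediction(cueset, o) for o in V.outcomes}
    return ActivationProfile(cues=cueset, activations=acts)


def discrimination_score(
    V: AssociationMatrix,
    n: int,
    coding: CueCoding,
    labels: Mapping[int, str],
    variant: str = "relative",
) -> float:
    """How well a featureless set of n objects picks out its own label.

    ``labels`` maps each in-scope set size to its label; ``n`` must be one of
    them.  The stimulus is numerosity cues only (``num1..num_n``), so feature
    cues cannot leak information.

    variants
    --------
    relative : activation of the correct label divided by the summed
        positive-part activations of all in-scope labels (0 if that sum is
        0; negative activations are floored at 0 inside the normalization).
        Lies in [0, 1] and is invariant to scaling V by a positive constant.
    raw : the single weight V(num_n, label_n), the direct strength of the
        discriminating mapping.
    share : cue informativity — the fraction of the label's total
        positive-part cue support contributed by its criterial set-size cue,
        V(num_n, label_n)+ / sum_c V(c, label_n)+.  This is the read-out
        that moves when competing cues are unlearned even though the
        criterial cue itself was never reinforced; also in [0, 1] and
        scale-invariant.
    """
    if n not in labels:
        raise ValueError(f"set size {n} is outside the labelled scope {sorted(labels)}")
    if variant == "raw":
        return V[f"{coding.numerosity_prefix}{n}", labels[n]]
    if variant == "share":
        label = labels[n]
        support = sum(max(V[c, label], 0.0) for c in V.cues)
        if support == 0:
            return 0.0
        return max(V[f"{coding.numerosity_prefix}{n}", label], 0.0) / support
    if variant != "relative":
        raise ValueError(f"unknown variant {variant!r}")
    profile = activate(V, coding.numerosity_cues(n))
    acts = np.array([profile[labels[k]] for k in labels])
    positive = np.clip(acts, 0.0, None)
    denom = positive.sum()
    if denom == 0:
        return 0.0
    return float(max(profile[labels[n]], 0.0) / denom)


def forced_choice(
    V: AssociationMatrix,
    target_label: str,
    candidate_sizes: Sequence[int],
    coding: CueCoding,
    policy: str = "argmax",
    rng: np.random.Generator | int | None = None,
    objects: Sequence[ObjectSet] | None = None,
) -> int:
    """Pick one of three candidate set sizes for a requested label.

    Each candidate is scored by the activation its cue set lends the target
    label.  ``argmax`` chooses the maximum (ties broken uniformly at random
    under the rng); ``luce`` samples proportionally to positive-part
    activations, falling back to uniform when no activation is positive.
    Candidates are featureless by default; pass ``objects`` to present full
    feature bundles instead.
    """
    if len(candidate_sizes) != 3:
        raise ValueError("forced choice requires exactly 3 candidate set sizes")
    if len(set(candidate_sizes)) != 3:
        raise ValueError("candidate set sizes must be distinct")
    if objects is None:
        objects = [ObjectSet(n) for n in candidate_sizes]
    elif [o.set_size for o in objects] != list(candidate_sizes):
        raise ValueError("objects must match candidate_sizes in order")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    acts = np.array(
        [activate(V, encode_set(o, coding))[target_label] for o in objects]
    )
    if policy == "argmax":
        winners = np.flatnonzero(acts == acts.max())
        idx = int(winners[0]) if len(winners) == 1 else int(rng.choice(winners))
    elif policy == "luce":
        positive = np.clip(acts, 0.0, None)
        total = positive.sum()
        p = positive / total if total > 0 else np.full(3, 1 / 3)
        idx = int(rng.choice(3, p=p))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return int(candidate_sizes[idx])


def forced_choice_accuracy(
    V: AssociationMatrix,
    trials: Sequence[tuple[str, Sequence[int], int]],
    coding: CueCoding,
    policy: str = "argmax",
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction correct over (target label, candidate sizes, correct size) trials."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    hits = sum(
        forced_choice(V, label, candidates, coding, policy=policy, rng=rng) == correct
        for label, candidates, correct in trials
    )
    return hits / len(trials)
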