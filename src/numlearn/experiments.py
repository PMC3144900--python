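"""Drivers composing the learner, the environment and the read-outs.

Three headline simulations:

* sim1 — sequencing: the same 2/4/6-object events trained Feature-to-Label
  (postnominal) versus Label-to-Feature (prenominal); FL devalues the
  unreliable color/shape/size cues through competition, LF ends up with
  plain conditional-probability weights and poor discrimination.
* sim2 — subitization: FL training on set sizes 1-20 weighted by spoken
  number-word frequency; small sets are discriminated quickly, large sets
  slowly or not at all, so a capacity-like limit emerges from a continuous
  learner.
* sim3 — facilitation: after 110 trials of frequency-weighted "natural"
  exposure, 18 structured FL trials on sets 2/4/6 improve discrimination of
  the untrained sizes 5 and 7 relative to 18 further natural trials
  (averaged over 5 replicate continuations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_stats import english_table, set_size_weights
from .learning_core import (
    AssociationMatrix,
    LearnerParams,
    Trajectory,
    Trial,
    train,
)
from .metrics import discrimination_score
from .number_world import (
    CueCoding,
    FeaturePools,
    ScheduleSpec,
    build_events,
    fl_block_246,
    make_trial,
    size_labels,
)

__all__ = [
    "Sim1Config",
    "Sim2Config",
    "Sim3Config",
    "Sim1Result",
    "Sim2Result",
    "Sim3Result",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "score_curves",
    "trials_to_half_max",
    "tail_mean_matrix",
    "cooccurrence_probs",
]


# --------------------------------------------------------------------------
# shared helpers

def score_curves(
    traj: Trajectory,
    sizes: Iterable[int],
    coding: CueCoding,
    labels: Mapping[int, str],
    variant: str = "relative",
    transpose: bool = False,
) -> pd.DataFrame:
    """Tidy discrimination-score curves: columns (trial, set_size, score).

    ``transpose`` scores a Label-to-Feature matrix by how well each label
    predicts the probe's cues (comprehension via generation).
    """
    rows = []
    for t, m in traj:
        mat = m.transposed() if transpose else m
        for n in sizes:
            rows.append((t, n, discrimination_score(mat, n, coding, labels, variant)))
    return pd.DataFrame(rows, columns=["trial", "set_size", "score"])


def trials_to_half_max(curve: pd.DataFrame, threshold: float | None = None) -> float:
    """First trial at which a score curve reaches a learnability threshold.

    ``curve`` has columns (trial, score).  ``threshold`` defaults to half
    the curve's own final value; passing half the score's known asymptote
    (0.5 for the normalized variants, lam/2 for raw weights) gives an index
    that is comparable across set sizes and robust to a noisy final value.
    Returns inf if the curve never gets there.
    """
    curve = curve.sort_values("trial")
    if threshold is None:
        final = curve["score"].iloc[-1]
        if final <= 0:
            return 0.0
        threshold = final / 2
    reached = curve[curve["score"] >= threshold]
    return float(reached["trial"].iloc[0]) if len(reached) else float("inf")


def tail_mean_matrix(traj: Trajectory, tail_fraction: float = 1 / 3) -> AssociationMatrix:
    """Average the snapshots over the last fraction of training.

    Under the delta rule, weights of intermittently reinforced pairs
    oscillate around lam * P(outcome | cue) at steady state; the time
    average is the quantity with the probabilistic interpretation.
    """
    last = traj.indices[-1]
    cutoff = last - tail_fraction * last
    tail = [m for t, m in traj if t > cutoff]
    out = tail[0].scaled(0.0)
    for m in tail:
        out = out + m
    return out.scaled(1.0 / len(tail))


def cooccurrence_probs(
    events: Sequence[tuple], coding: CueCoding
) -> dict[tuple[str, str], float]:
    """Empirical P(cue | label) over (ObjectSet, label) events."""
    from .number_world import encode_set

    label_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for obj, label in events:
        label_counts[label] = label_counts.get(label, 0) + 1
        for cue in encode_set(obj, coding):
            pair_counts[(label, cue)] = pair_counts.get((label, cue), 0) + 1
    return {
        (label, cue): cnt / label_counts[label]
        for (label, cue), cnt in pair_counts.items()
    }


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# --------------------------------------------------------------------------
# Simulation 1: FL vs LF sequencing

@dataclass(frozen=True)
class Sim1Config:
    sizes: tuple[int, ...] = (2, 4, 6)
    n_trials: int = 600
    record_every: int = 1
    seed: int = 0
    params: LearnerParams = LearnerParams()
    pools: FeaturePools = FeaturePools()


@dataclass
class Sim1Result:
    config: Sim1Config
    events: list
    fl: Trajectory
    lf: Trajectory
    coding: CueCoding
    labels: dict[int, str]

    def weight_curves(self, label: str) -> pd.DataFrame:
        """Weights of every cue onto ``label`` over training, both arms.

        FL reads V(cue, label); LF reads the mirror V(label, cue)."""
        rows = []
        for arm, traj in (("FL", self.fl), ("LF", self.lf)):
            for t, m in traj:
                mat = m if arm == "FL" else m.transposed()
                for cue in mat.cues:
                    rows.append((arm, t, cue, label, mat[cue, label]))
        return pd.DataFrame(rows, columns=["arm", "trial", "cue", "outcome", "value"])

    def final_scores(self, variant: str = "relative") -> pd.DataFrame:
        fl = score_curves(self.fl, self.labels, self.coding, self.labels, variant)
        lf = score_curves(
            self.lf, self.labels, self.coding, self.labels, variant, transpose=True
        )
        last = self.fl.indices[-1]
        out = pd.merge(
            fl[fl["trial"] == last].rename(columns={"score": "fl_score"}),
            lf[lf["trial"] == last].rename(columns={"score": "lf_score"}),
            on=["trial", "set_size"],
        )
        return out[["set_size", "fl_score", "lf_score"]]


def run_sim1(cfg: Sim1Config = Sim1Config()) -> Sim1Result:
    """Train mirrored FL and LF arms on identical 2/4/6 events."""
    coding = CueCoding(include_features=True)
    spec = ScheduleSpec(
        sizes=cfg.sizes, n_trials=cfg.n_trials, mode="equal", seed=cfg.seed
    )
    events = build_events(spec, cfg.pools, coding)
    fl_stream = [make_trial(o, l, "FL", coding) for o, l in events]
    lf_stream = [make_trial(o, l, "LF", coding) for o, l in events]
    fl = train(fl_stream, cfg.params, cfg.record_every)
    lf = train(lf_stream, cfg.params, cfg.record_every)
    return Sim1Result(
        config=cfg,
        events=events,
        fl=fl,
        lf=lf,
        coding=coding,
        labels=size_labels(cfg.sizes),
    )


# --------------------------------------------------------------------------
# Simulation 2: frequency-weighted training and subitization

@dataclass(frozen=True)
class Sim2Config:
    """Frequency-weighted training on sets 1-20.

    The learning rate defaults to beta=0.05 here rather than the global
    0.2: with nested coding a size-n set co-activates n cues and the
    summed prediction moves by n*alpha*beta of the discrepancy per trial,
    so the delta rule is divergently oscillatory once n*alpha*beta
    exceeds 2.  Sets of up to 20 objects therefore need
    alpha*beta <= 0.1 for damped learning (0.05 keeps every set size
    monotonically convergent); the smaller simulations, with at most 10
    co-active cues, keep the 0.2 default.
    """

    max_size: int = 20
    n_trials: int = 1000
    record_every: int = 10
    seed: int = 0
    arm: str = "weighted"  # "weighted" (sizes 1-20, spoken frequency) or
    # "equal8" (sizes 1-8, equal frequency)
    eval_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    include_features: bool = False
    params: LearnerParams = LearnerParams(beta=0.05)
    pools: FeaturePools = FeaturePools()


@dataclass
class Sim2Result:
    config: Sim2Config
    trajectory: Trajectory
    coding: CueCoding
    labels: dict[int, str]
    weights: dict[int, float] | None

    def scores(self, variant: str = "relative") -> pd.DataFrame:
        """Score curves for the evaluated sizes, judged against the full
        trained label lexicon (so late-lexicon confusions count)."""
        return score_curves(
            self.trajectory, self.config.eval_sizes, self.coding, self.labels, variant
        )

    def final_scores(self, variant: str = "relative") -> pd.Series:
        df = self.scores(variant)
        last = self.trajectory.indices[-1]
        return df[df["trial"] == last].set_index("set_size")["score"]

    def half_max_trials(self, variant: str = "raw") -> pd.Series:
        """Trials to reach half the score asymptote, per evaluated size."""
        threshold = self.config.params.lam / 2 if variant == "raw" else 0.5
        df = self.scores(variant)
        return df.groupby("set_size").apply(
            lambda g: trials_to_half_max(g[["trial", "score"]], threshold),
            include_groups=False,
        )


def run_sim2(cfg: Sim2Config = Sim2Config()) -> Sim2Result:
    """FL training on a frequency-weighted (or equal) set-size diet."""
    coding = CueCoding(include_features=cfg.include_features)
    if cfg.arm == "weighted":
        weights = set_size_weights(cfg.max_size)
        sizes = tuple(sorted(weights))
        spec = ScheduleSpec(
            sizes=sizes,
            n_trials=cfg.n_trials,
            weights=tuple(weights[n] for n in sizes),
            mode="weighted-deterministic",
            seed=cfg.seed,
        )
    elif cfg.arm == "equal8":
        weights = None
        sizes = tuple(range(1, 9))
        spec = ScheduleSpec(
            sizes=sizes, n_trials=cfg.n_trials, mode="equal", seed=cfg.seed
        )
    else:
        raise ValueError(f"unknown sim2 arm {cfg.arm!r}")
    missing = [n for n in cfg.eval_sizes if n not in sizes]
    if missing:
        raise ValueError(f"eval sizes {missing} not in the training scope")
    stream = [
        make_trial(o, l, "FL", coding)
        for o, l in build_events(spec, cfg.pools, coding)
    ]
    traj = train(stream, cfg.params, cfg.record_every)
    return Sim2Result(
        config=cfg,
        trajectory=traj,
        coding=coding,
        labels=size_labels(sizes),
        weights=weights,
    )


# --------------------------------------------------------------------------
# Simulation 3: structured FL blocks after natural exposure

@dataclass(frozen=True)
class Sim3Config:
    pretrain_trials: int = 110
    fl_blocks: int = 6
    baseline_extra: int = 18
    baseline_reps: int = 5
    record_every: int = 1
    seed: int = 0
    eval_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    params: LearnerParams = LearnerParams()
    pools: FeaturePools = FeaturePools()


@dataclass
class Sim3Result:
    config: Sim3Config
    treatment: Trajectory
    baselines: list[Trajectory]
    coding: CueCoding
    labels: dict[int, str]

    def improvement_table(self, variant: str = "share") -> pd.DataFrame:
        """Score at end of pretraining vs end of run, per size and arm.

        Defaults to the cue-informativity share, the read-out that captures
        unlearning of competing cues to labels that were never reinforced.
        Baseline scores are averaged over the replicate continuations."""
        t0 = self.config.pretrain_trials
        t1 = t0 + 3 * self.config.fl_blocks
        rows = []
        for n in self.config.eval_sizes:
            s_pre = discrimination_score(
                self.treatment.at(t0), n, self.coding, self.labels, variant
            )
            s_treat = discrimination_score(
                self.treatment.at(t1), n, self.coding, self.labels, variant
            )
            s_base = float(
                np.mean(
                    [
                        discrimination_score(b.at(t1), n, self.coding, self.labels, variant)
                        for b in self.baselines
                    ]
                )
            )
            rows.append((n, s_pre, s_treat, s_base, s_treat - s_pre, s_base - s_pre))
        return pd.DataFrame(
            rows,
            columns=[
                "set_size",
                "score_pre",
                "score_treatment",
                "score_baseline",
                "improvement_treatment",
                "improvement_baseline",
            ],
        )

    def facilitation_by_replicate(
        self, sizes: tuple[int, ...] = (5, 7), variant: str = "share"
    ) -> pd.DataFrame:
        """Treatment-vs-baseline improvement against each replicate separately.

        Useful for checking that the untrained-number facilitation is not an
        artifact of one lucky baseline continuation."""
        t0 = self.config.pretrain_trials
        t1 = t0 + 3 * self.config.fl_blocks
        rows = []
        for n in sizes:
            pre = discrimination_score(
                self.treatment.at(t0), n, self.coding, self.labels, variant
            )
            treat = discrimination_score(
                self.treatment.at(t1), n, self.coding, self.labels, variant
            )
            for rep, b in enumerate(self.baselines):
                base = discrimination_score(b.at(t1), n, self.coding, self.labels, variant)
                rows.append((n, rep, treat - pre, base - pre, treat - pre > base - pre))
        return pd.DataFrame(
            rows,
            columns=[
                "set_size",
                "replicate",
                "improvement_treatment",
                "improvement_baseline",
                "treatment_exceeds",
            ],
        )


def run_sim3(cfg: Sim3Config = Sim3Config()) -> Sim3Result:
    """Natural pretraining, then structured FL blocks vs natural continuation.

    The pretraining stream is built once and shared bit-for-bit by both
    arms.  The treatment arm appends ``fl_blocks`` ascending 2/4/6 blocks;
    each baseline replicate appends ``baseline_extra`` further trials
    sampled from the natural frequency distribution under its own seed.
    """
    coding = CueCoding(include_features=True)
    table = english_table()
    sizes = table.numbers
    seeds = _spawn_seeds(cfg.seed, 1 + cfg.baseline_reps)
    pre_spec = ScheduleSpec(
        sizes=sizes,
        n_trials=cfg.pretrain_trials,
        weights=tuple(table.frequencies),
        mode="weighted-deterministic",
        seed=seeds[0],
    )
    pre_events = build_events(pre_spec, cfg.pools, coding)
    pre_stream = [make_trial(o, l, "FL", coding) for o, l in pre_events]

    treatment_stream = pre_stream + fl_block_246(cfg.fl_blocks, cfg.pools, coding)
    treatment = train(treatment_stream, cfg.params, cfg.record_every)

    baselines = []
    for rep_seed in seeds[1:]:
        extra_spec = ScheduleSpec(
            sizes=sizes,
            n_trials=cfg.baseline_extra,
            weights=tuple(table.frequencies),
            mode="weighted-sampled",
            seed=rep_seed,
        )
        extra = [
            make_trial(o, l, "FL", coding)
            for o, l in build_events(extra_spec, cfg.pools, coding)
        ]
        baselines.append(train(pre_stream + extra, cfg.params, cfg.record_every))
    return Sim3Result(
        config=cfg,
        treatment=treatment,
        baselines=baselines,
        coding=coding,
        labels=size_labels(cfg.eval_sizes),
    )
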