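"""Rescorla-Wagner error-driven learning engine.

The learner maintains a matrix of predictive values V(cue, outcome). On each
discrete trial a set of cues and a set of outcomes co-occur; for every outcome
``o`` in the learner's (fixed) lexicon the summed prediction of the cues
present is compared with the outcome's asymptote — ``lam`` if ``o`` occurred,
0 if it did not — and each present cue's weight moves a fraction
``alpha * beta`` of that discrepancy.  Cues that are absent on a trial are
untouched.  Because all co-present cues share one discrepancy, cues compete
for a finite amount of predictive value, which is what produces blocking,
overexpectation and the devaluation of unreliable cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LearnerParams",
    "Trial",
    "AssociationMatrix",
    "Trajectory",
    "update_trial",
    "train",
    "read_event_stream",
    "write_event_stream",
]


@dataclass(frozen=True)
class LearnerParams:
    """Parameters of the delta-rule update.

    alpha : cue saliency in [0, 1]; 1 removes its influence.
    beta  : learning rate in [0, 1].
    lam   : outcome asymptote (the total predictive value an outcome
            can support); expressed on a 0-100 scale by default.
    """

    alpha: float = 1.0
    beta: float = 0.2
    lam: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")


@dataclass(frozen=True)
class Trial:
    """One learning event: the cues present and the outcomes that occurred.

    ``outcomes`` may be empty (an extinction trial); ``cues`` may not.
    Cue and outcome identifiers live in disjoint namespaces.
    """

    cues: frozenset[str]
    outcomes: frozenset[str]

    def __init__(self, cues: Iterable[str], outcomes: Iterable[str] = ()) -> None:
        object.__setattr__(self, "cues", frozenset(cues))
        object.__setattr__(self, "outcomes", frozenset(outcomes))
        if not self.cues:
            raise ValueError("a trial must have at least one cue")
        overlap = self.cues & self.outcomes
        if overlap:
            raise ValueError(
                f"cue and outcome namespaces must be disjoint; shared: {sorted(overlap)}"
            )


class AssociationMatrix:
    """Predictive values V indexed by (cue, outcome); absent pairs read as 0."""

    __slots__ = ("_cue_index", "_out_index", "_v")

    def __init__(
        self,
        cues: Iterable[str] = (),
        outcomes: Iterable[str] = (),
        values: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        self._cue_index: dict[str, int] = {c: i for i, c in enumerate(dict.fromkeys(cues))}
        self._out_index: dict[str, int] = {o: i for i, o in enumerate(dict.fromkeys(outcomes))}
        self._v = np.zeros((len(self._cue_index), len(self._out_index)))
        if values:
            for (c, o), val in values.items():
                self[c, o] = val

    # -- vocabulary ---------------------------------------------------------

    @property
    def cues(self) -> tuple[str, ...]:
        return tuple(self._cue_index)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self._out_index)

    def ensure(self, cues: Iterable[str] = (), outcomes: Iterable[str] = ()) -> None:
        """Grow the matrix with zero rows/columns for unseen identifiers."""
        new_c = [c for c in cues if c not in self._cue_index]
        new_o = [o for o in outcomes if o not in self._out_index]
        if new_c:
            for c in new_c:
                self._cue_index[c] = len(self._cue_index)
            self._v = np.vstack([self._v, np.zeros((len(new_c), self._v.shape[1]))])
        if new_o:
            for o in new_o:
                self._out_index[o] = len(self._out_index)
            self._v = np.hstack([self._v, np.zeros((self._v.shape[0], len(new_o)))])

    # -- element access -----------------------------------------------------

    def __getitem__(self, key: tuple[str, str]) -> float:
        cue, outcome = key
        ci = self._cue_index.get(cue)
        oi = self._out_index.get(outcome)
        if ci is None or oi is None:
            return 0.0
        return float(self._v[ci, oi])

    def __setitem__(self, key: tuple[str, str], value: float) -> None:
        cue, outcome = key
        self.ensure([cue], [outcome])
        self._v[self._cue_index[cue], self._out_index[outcome]] = value

    def summed_prediction(self, cues: Iterable[str], outcome: str) -> float:
        """Total prediction of ``outcome`` from the given co-present cues."""
        oi = self._out_index.get(outcome)
        if oi is None:
            return 0.0
        rows = [self._cue_index[c] for c in cues if c in self._cue_index]
        return float(self._v[rows, oi].sum()) if rows else 0.0

    def is_finite(self) -> bool:
        return bool(np.isfinite(self._v).all())

    # -- structural ops -----------------------------------------------------

    def copy(self) -> "AssociationMatrix":
        out = AssociationMatrix()
        out._cue_index = dict(self._cue_index)
        out._out_index = dict(self._out_index)
        out._v = self._v.copy()
        return out

    def transposed(self) -> "AssociationMatrix":
        """Swap the cue and outcome roles (V'(a, b) = V(b, a))."""
        out = AssociationMatrix()
        out._cue_index = dict(self._out_index)
        out._out_index = dict(self._cue_index)
        out._v = self._v.T.copy()
        return out

    def __add__(self, other: "AssociationMatrix") -> "AssociationMatrix":
        out = self.copy()
        out.ensure(other.cues, other.outcomes)
        for c in other.cues:
            for o in other.outcomes:
                out[c, o] = out[c, o] + other[c, o]
        return out

    def scaled(self, factor: float) -> "AssociationMatrix":
        out = self.copy()
        out._v = out._v * factor
        return out

    def to_frame(self, include_zeros: bool = True) -> pd.DataFrame:
        """Tidy view with columns (cue, outcome, value)."""
        records = [
            (c, o, float(self._v[ci, oi]))
            for c, ci in self._cue_index.items()
            for o, oi in self._out_index.items()
        ]
        df = pd.DataFrame(records, columns=["cue", "outcome", "value"])
        if not include_zeros:
            df = df[df["value"] != 0.0].reset_index(drop=True)
        return df

    def __repr__(self) -> str:  # pragma: no cover
        return f"AssociationMatrix({len(self._cue_index)} cues x {len(self._out_index)} outcomes)"


@dataclass
class Trajectory:
    """Time-indexed record of the association matrix over training.

    ``snapshots`` holds (trial index, matrix copy) pairs; index t means
    "after t trials", so index 0 is the all-zero starting state.
    """

    snapshots: list[tuple[int, AssociationMatrix]] = field(default_factory=list)
    record_every: int = 1

    def __post_init__(self) -> None:
        idx = [t for t, _ in self.snapshots]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("snapshot trial indices must be strictly increasing")

    @property
    def indices(self) -> list[int]:
        return [t for t, _ in self.snapshots]

    @property
    def final(self) -> AssociationMatrix:
        return self.snapshots[-1][1]

    def at(self, trial: int) -> AssociationMatrix:
        """Snapshot at the largest recorded index <= ``trial``."""
        candidates = [(t, m) for t, m in self.snapshots if t <= trial]
        if not candidates:
            raise KeyError(f"no snapshot at or before trial {trial}")
        return candidates[-1][1]

    def __iter__(self) -> Iterator[tuple[int, AssociationMatrix]]:
        return iter(self.snapshots)

    def to_frame(self, include_zeros: bool = False) -> pd.DataFrame:
        """Tidy long frame with columns (trial, cue, outcome, value)."""
        frames = []
        for t, m in self.snapshots:
            df = m.to_frame(include_zeros=include_zeros)
            df.insert(0, "trial", t)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str | Path, include_zeros: bool = False) -> None:
        self.to_frame(include_zeros=include_zeros).to_csv(path, sep="\t", index=False)


def update_trial(
    V: AssociationMatrix,
    trial: Trial,
    known_outcomes: Iterable[str],
    params: LearnerParams = LearnerParams(),
    inplace: bool = False,
) -> AssociationMatrix:
    """Apply one delta-rule update and return the updated matrix.

    For every cue present on the trial and every outcome in the fixed
    lexicon ``known_outcomes``::

        dV(c, o) = alpha * beta * (lam_o - sum_j V(c_j, o))

    where ``lam_o = params.lam`` if the outcome occurred and 0 otherwise,
    and the sum runs over the cues present, using pre-update values
    (the within-trial update is simultaneous).  Outcomes that occur but are
    not in the lexicon are an error — the lexicon must be fixed up front so
    that every trial can unlearn erroneous predictions of absent outcomes.
    """
    known = list(dict.fromkeys(known_outcomes))
    missing = trial.outcomes.difference(known)
    if missing:
        raise ValueError(
            f"trial outcomes {sorted(missing)} are not in the known-outcome lexicon"
        )
    out = V if inplace else V.copy()
    out.ensure(trial.cues, known)
    if not out.is_finite():
        raise ValueError("association matrix contains NaN or infinite values")

    rows = np.array([out._cue_index[c] for c in trial.cues])
    cols = np.array([out._out_index[o] for o in known])
    totals = out._v[np.ix_(rows, cols)].sum(axis=0)
    lam_vec = np.array([params.lam if o in trial.outcomes else 0.0 for o in known])
    delta = params.alpha * params.beta * (lam_vec - totals)
    out._v[np.ix_(rows, cols)] += delta  # same delta for every present cue
    return out


def train(
    stream: Sequence[Trial],
    params: LearnerParams = LearnerParams(),
    record_every: int = 1,
) -> Trajectory:
    """Train from zero weights on an ordered trial stream.

    The outcome lexicon is the union of outcomes across the whole stream,
    fixed before the first trial.  Snapshots are taken at trial 0, every
    ``record_every`` trials, and after the final trial.  Deterministic.
    """
    if not stream:
        raise ValueError("cannot train on an empty trial stream")
    if record_every < 1:
        raise ValueError("record_every must be a positive integer")
    all_cues: dict[str, None] = {}
    all_outcomes: dict[str, None] = {}
    for tr in stream:
        all_cues.update(dict.fromkeys(sorted(tr.cues)))
        all_outcomes.update(dict.fromkeys(sorted(tr.outcomes)))
    known = list(all_outcomes)

    V = AssociationMatrix(cues=all_cues, outcomes=known)
    snapshots: list[tuple[int, AssociationMatrix]] = [(0, V.copy())]
    for t, tr in enumerate(stream, start=1):
        update_trial(V, tr, known, params, inplace=True)
        if t % record_every == 0 or t == len(stream):
            snapshots.append((t, V.copy()))
    return Trajectory(snapshots=snapshots, record_every=record_every)


# -- event-stream text format ----------------------------------------------
#
# One trial per line: comma-joined cues, a tab, comma-joined outcomes.
# An extinction trial has nothing after the tab.

_FORBIDDEN = ("\t", ",", "\n")


def _check_ids(ids: Iterable[str]) -> None:
    for ident in ids:
        if any(ch in ident for ch in _FORBIDDEN):
            raise ValueError(f"identifier {ident!r} contains a reserved character")


def write_event_stream(stream: Sequence[Trial], path: str | Path) -> None:
    lines = []
    for tr in stream:
        _check_ids(tr.cues)
        _check_ids(tr.outcomes)
        lines.append(f"{','.join(sorted(tr.cues))}\t{','.join(sorted(tr.outcomes))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_stream(path: str | Path) -> list[Trial]:
    trials = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            cue_field, outcome_field = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"line {lineno}: expected exactly one tab separator") from exc
        cues = [c for c in cue_field.split(",") if c]
        outcomes = [o for o in outcome_field.split(",") if o]
        trials.append(Trial(cues=cues, outcomes=outcomes))
    return trials
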