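"""Unit and property tests for the delta-rule learning engine."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from numlearn.learning_core import (
    AssociationMatrix,
    LearnerParams,
    Trajectory,
    Trial,
    read_event_stream,
    train,
    update_trial,
    write_event_stream,
)

DEFAULTS = LearnerParams()


def matrix_from(values):
    m = AssociationMatrix()
    for (c, o), v in values.items():
        m[c, o] = v
    return m


class TestParamsAndTrialValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": -0.1}, {"alpha": 1.1}, {"beta": 2.0}, {"lam": 0.0}]
    )
    def test_out_of_range_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LearnerParams(**kwargs)

    def test_defaults_are_headline_setting(self):
        assert (DEFAULTS.alpha, DEFAULTS.beta, DEFAULTS.lam) == (1.0, 0.2, 100.0)

    def test_trial_needs_cues_and_disjoint_namespaces(self):
        with pytest.raises(ValueError):
            Trial(cues=[], outcomes=["X"])
        with pytest.raises(ValueError):
            Trial(cues=["A"], outcomes=["A"])

    def test_extinction_trial_allowed(self):
        assert Trial(cues=["A"]).outcomes == frozenset()


class TestUpdateTrial:
    @pytest.mark.parametrize(
        "initial, cues, outcomes, checked, expected_delta",
        [
            # acquisition from zero: 0.2 * (100 - 0)
            ({}, {"A"}, {"X"}, ("A", "X"), 20.0),
            # at asymptote nothing changes
            ({("A", "X"): 100.0}, {"A"}, {"X"}, ("A", "X"), 0.0),
            # overexpectation: two trained cues overshoot jointly
            (
                {("A", "X"): 60.0, ("B", "X"): 60.0},
                {"A", "B"},
                {"X"},
                ("A", "X"),
                0.2 * (100 - 120),
            ),
            # absent outcome with nonzero prediction is unlearned
            ({("A", "Y"): 50.0}, {"A"}, {"X"}, ("A", "Y"), 0.2 * (0 - 50)),
        ],
    )
    def test_single_step_deltas(self, initial, cues, outcomes, checked, expected_delta):
        V = matrix_from(initial)
        before = V[checked]
        out = update_trial(V, Trial(cues, outcomes), {"X", "Y"}, DEFAULTS)
        assert out[checked] == pytest.approx(before + expected_delta)

    def test_update_is_simultaneous_and_symmetric(self):
        V = matrix_from({("A", "X"): 60.0, ("B", "X"): 60.0})
        out = update_trial(V, Trial({"A", "B"}, {"X"}), {"X"}, DEFAULTS)
        # both cues see the same pre-update summed prediction
        assert out["A", "X"] == pytest.approx(out["B", "X"]) == pytest.approx(56.0)

    def test_absent_cues_untouched(self):
        V = matrix_from({("C", "X"): 30.0})
        out = update_trial(V, Trial({"A"}, {"X"}), {"X"}, DEFAULTS)
        assert out["C", "X"] == 30.0

    def test_outcome_outside_lexicon_is_an_error(self):
        with pytest.raises(ValueError, match="lexicon"):
            update_trial(AssociationMatrix(), Trial({"A"}, {"X"}), {"Y"}, DEFAULTS)

    def test_non_finite_matrix_is_an_error(self):
        V = matrix_from({("A", "X"): math.nan})
        with pytest.raises(ValueError, match="NaN"):
            update_trial(V, Trial({"A"}, {"X"}), {"X"}, DEFAULTS)

    @given(
        weights=st.lists(
            st.floats(min_value=-50, max_value=150), min_size=1, max_size=4
        )
    )
    def test_extinction_only_decreases_or_preserves_touched_weights(self, weights):
        cues = [f"c{i}" for i in range(len(weights))]
        V = matrix_from({(c, "X"): w for c, w in zip(cues, weights)})
        out = update_trial(V, Trial(cues, set()), {"X"}, DEFAULTS)
        total = sum(weights)
        for c, w in zip(cues, weights):
            if total > 0:
                assert out[c, "X"] < w
            elif total == 0:
                assert out[c, "X"] == w


class TestTrain:
    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            train([], DEFAULTS)

    def test_single_cue_acquisition_matches_closed_form(self):
        stream = [Trial({"A"}, {"X"})] * 40
        traj = train(stream, DEFAULTS, record_every=1)
        for t, m in traj:
            expected = DEFAULTS.lam * (1 - (1 - DEFAULTS.alpha * DEFAULTS.beta) ** t)
            assert m["A", "X"] == pytest.approx(expected, abs=1e-9)
        assert traj.final["A", "X"] == pytest.approx(
            100 * (1 - 0.8**40), abs=1e-9
        )

    def test_five_trial_value(self):
        traj = train([Trial({"A"}, {"X"})] * 5, DEFAULTS)
        assert traj.final["A", "X"] == pytest.approx(67.232, abs=1e-9)

    def test_negatively_accelerated_curve(self):
        traj = train([Trial({"A"}, {"X"})] * 30, DEFAULTS, record_every=1)
        values = [m["A", "X"] for _, m in traj]
        deltas = [abs(b - a) for a, b in zip(values, values[1:])]
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(deltas, deltas[1:]))

    def test_summed_prediction_converges_to_lambda_without_diverging(self):
        stream = [Trial({"A", "B", "C"}, {"X"})] * 200
        traj = train(stream, DEFAULTS, record_every=1)
        sums = [m.summed_prediction({"A", "B", "C"}, "X") for _, m in traj]
        assert max(sums) <= DEFAULTS.lam + 1e-9
        assert sums[-1] == pytest.approx(DEFAULTS.lam, abs=1e-6)

    def test_blocking(self):
        # A->X pretraining blocks B in the later {A,B}->X compound phase
        compound = [Trial({"A", "B"}, {"X"})] * 50
        pretrained = train([Trial({"A"}, {"X"})] * 50 + compound, DEFAULTS)
        control = train(compound, DEFAULTS)
        assert pretrained.final["B", "X"] < 1.0
        assert pretrained.final["B", "X"] < control.final["B", "X"]

    def test_label_to_feature_weights_average_to_lambda_times_probability(self):
        # a single label cue with a feature present on alternate trials:
        # the steady-state time-average of V is lam * P(feature | label)
        stream = [
            Trial({"L"}, {"f"} if t % 2 == 0 else set()) for t in range(2000)
        ]
        traj = train(stream, DEFAULTS, record_every=1)
        tail = [m["L", "f"] for t, m in traj if t > 1500]
        assert np.mean(tail) == pytest.approx(50.0, abs=1.0)

    def test_snapshots_start_at_zero_and_end_at_final_trial(self):
        traj = train([Trial({"A"}, {"X"})] * 25, DEFAULTS, record_every=10)
        assert traj.indices == [0, 10, 20, 25]
        assert traj.snapshots[0][1]["A", "X"] == 0.0

    def test_deterministic(self):
        stream = [Trial({"A", "B"}, {"X"})] * 10 + [Trial({"A"}, set())] * 5
        a = train(stream, DEFAULTS).final
        b = train(stream, DEFAULTS).final
        assert a.to_frame().equals(b.to_frame())


class TestTrajectoryAndIO:
    def test_trajectory_indices_must_increase(self):
        m = AssociationMatrix()
        with pytest.raises(ValueError):
            Trajectory(snapshots=[(0, m), (0, m)])

    def test_tidy_export_columns(self, tmp_path):
        traj = train([Trial({"A"}, {"X"})] * 3, DEFAULTS)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path, include_zeros=True)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["trial", "cue", "outcome", "value"]
        assert set(df["trial"]) == {0, 1, 2, 3}

    def test_event_stream_round_trip(self, tmp_path):
        stream = [
            Trial({"num1", "num2", "color:red"}, {"two"}),
            Trial({"L"}, set()),
            Trial({"a"}, {"x", "y"}),
        ]
        path = tmp_path / "events.tsv"
        write_event_stream(stream, path)
        assert read_event_stream(path) == stream

    def test_reserved_characters_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_event_stream([Trial({"a,b"}, {"x"})], tmp_path / "bad.tsv")
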