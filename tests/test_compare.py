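"""Edit distance, trace replay and the two drift analyses."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behaviorflow.compare import (
    DifferenceSet,
    WeightConfig,
    daily_outlier_series,
    edwa,
    weekly_drift_curves,
    weighted_distance,
    wiaa,
)
from behaviorflow.eventlog import EventLog
from behaviorflow.inference import infer_tpa
from behaviorflow.tpa import END, START

from conftest import DAY0, make_log, make_trace, random_log, random_tpa


class TestEdwa:
    def test_identity_empty(self):
        rng = np.random.default_rng(31)
        tpa = random_tpa(rng)
        diffs = edwa(tpa, tpa)
        assert diffs.is_empty()
        assert weighted_distance(diffs) == 0

    def test_superset_model_adds(self):
        a = infer_tpa(make_log([["X", "Y"]]))
        b = infer_tpa(make_log([["X", "Y", "Z"]]))
        diffs = edwa(b, a)
        assert diffs.added_nodes == ["Z"]
        assert diffs.added_transitions == [("Y", "Z")]
        assert diffs.deleted_nodes == [] and diffs.deleted_transitions == []

    def test_swap_symmetry(self):
        a = infer_tpa(make_log([["X", "Y"]]))
        b = infer_tpa(make_log([["X", "Y", "Z"]]))
        ab, ba = edwa(a, b), edwa(b, a)
        assert ab.deleted_nodes == ba.added_nodes == ["Z"]
        assert ab.deleted_transitions == ba.added_transitions == [("Y", "Z")]

    def test_virtual_start_excluded_from_nodes_but_not_transitions(self):
        a = infer_tpa(make_log([["X"]]))
        b = infer_tpa(make_log([["Y"]]))
        diffs = edwa(a, b)
        assert START not in diffs.added_nodes + diffs.deleted_nodes
        assert (START, "X") in diffs.added_transitions
        assert (START, "Y") in diffs.deleted_transitions


class TestWeightedDistance:
    def test_empty_is_zero(self):
        assert weighted_distance(DifferenceSet(), WeightConfig(9, 9, 9, 9)) == 0

    def test_direct_evaluation(self):
        diffs = DifferenceSet(
            added_nodes=["a", "b"],
            deleted_nodes=["c"],
            added_transitions=[("a", "b"), ("b", "c"), ("c", "a")],
        )
        assert weighted_distance(diffs, WeightConfig(2, 2, 1, 1)) == 9

    def test_default_node_weight_doubles_transition(self):
        one_node = DifferenceSet(added_nodes=["a"])
        one_trans = DifferenceSet(added_transitions=[("a", "b")])
        assert weighted_distance(one_node) == 2 * weighted_distance(one_trans) == 2

    @settings(deadline=None, max_examples=50)
    @given(
        sizes=st.tuples(*[st.integers(0, 6)] * 4),
        weights=st.tuples(*[st.floats(0, 10, allow_nan=False)] * 4),
    )
    def test_linear_in_list_sizes_and_weights(self, sizes, weights):
        na, nd, ta, td = sizes
        diffs = DifferenceSet(
            added_nodes=[f"n{i}" for i in range(na)],
            deleted_nodes=[f"d{i}" for i in range(nd)],
            added_transitions=[(f"s{i}", "t") for i in range(ta)],
            deleted_transitions=[(f"u{i}", "t") for i in range(td)],
        )
        w = WeightConfig(*weights)
        expected = weights[0] * na + weights[1] * nd + weights[2] * ta + weights[3] * td
        assert weighted_distance(diffs, w) == pytest.approx(expected)


class TestWiaa:
    def test_training_traces_accepted(self):
        rng = np.random.default_rng(33)
        log = random_log(rng, 20)
        tpa = infer_tpa(log)
        for trace in log.traces:
            res = wiaa(tpa, trace)
            assert res.accepted and res.distance == 0

    def test_unknown_area_scored_by_hand(self):
        tpa = infer_tpa(make_log([["A", "B"]]))
        res = wiaa(tpa, make_trace(["A", "C"]))
        assert not res.accepted
        assert res.differences.added_nodes == ["C"]
        assert res.differences.added_transitions == [("A", "C")]
        assert res.distance == 3  # 2*1 node + 1*1 transition

    def test_nonfinal_terminal_recorded(self):
        tpa = infer_tpa(make_log([["A", "B"]]))
        res = wiaa(tpa, make_trace(["A"]))
        assert not res.accepted
        assert (("A", END)) in res.differences.added_transitions
        assert res.distance == 1

    def test_distance_consistent_with_weighted_differences(self):
        rng = np.random.default_rng(34)
        for _ in range(20):
            tpa = infer_tpa(random_log(rng, 5))
            trace = random_log(rng, 1).traces[0]
            res = wiaa(tpa, trace)
            assert res.distance == weighted_distance(res.differences)
            assert res.distance >= 0

    def test_empty_trace_rejected(self):
        from behaviorflow.eventlog import Trace

        tpa = infer_tpa(make_log([["A"]]))
        with pytest.raises(ValueError):
            wiaa(tpa, Trace("R1", DAY0, ()))


class TestDailyOutlierSeries:
    def test_identical_behavior_scores_zero(self):
        model = make_log([["A", "B"], ["A", "B"]])
        eval_traces = [
            make_trace(["A", "B"], day=DAY0 + dt.timedelta(days=10 + i))
            for i in range(3)
        ]
        series = daily_outlier_series(model, EventLog(traces=eval_traces))
        assert series.values == [0.0, 0.0, 0.0]

    def test_single_day_series(self):
        model = make_log([["A", "B"]])
        eval_log = EventLog(traces=[make_trace(["A", "B"], day=DAY0 + dt.timedelta(days=5))])
        series = daily_outlier_series(model, eval_log)
        assert len(series) == 1

    def test_overlapping_periods_warn(self):
        model = make_log([["A", "B"]])
        with pytest.warns(UserWarning):
            daily_outlier_series(model, model)


class TestWeeklyDriftCurves:
    def test_identical_weeks_all_zero(self):
        # same daily routine repeated over three ISO weeks (Mon-aligned)
        start = dt.date(2024, 1, 1)  # a Monday
        traces = [
            make_trace(["A", "B", "C"], day=start + dt.timedelta(days=i))
            for i in range(21)
        ]
        absolute, relative = weekly_drift_curves(EventLog(traces=traces))
        assert absolute.values == [0.0, 0.0]
        assert relative.values == [0.0, 0.0]

    def test_two_week_log_series_equal(self):
        start = dt.date(2024, 1, 1)
        traces = [
            make_trace(["A", "B"], day=start + dt.timedelta(days=i)) for i in range(7)
        ] + [
            make_trace(["A", "C"], day=start + dt.timedelta(days=7 + i))
            for i in range(7)
        ]
        absolute, relative = weekly_drift_curves(EventLog(traces=traces))
        assert len(absolute) == len(relative) == 1
        assert absolute.values == relative.values
        # hand count: node C added (2), B deleted (2), A->C added (1),
        # A->B deleted (1) => 6 under default 2:1 weights
        assert absolute.values[0] == 6.0

    def test_gap_week_flagged(self):
        start = dt.date(2024, 1, 1)
        days = list(range(7)) + list(range(14, 21))  # week 2 missing
        traces = [
            make_trace(["A", "B"], day=start + dt.timedelta(days=i)) for i in days
        ]
        absolute, _ = weekly_drift_curves(EventLog(traces=traces))
        assert absolute.metadata["skipped_weeks"] == ["2024-W02"]

    def test_requires_two_weeks(self):
        with pytest.raises(ValueError):
            weekly_drift_curves(make_log([["A", "B"]]))


def test_distance_symmetry_under_symmetric_weights():
    rng = np.random.default_rng(35)
    for _ in range(20):
        a, b = random_tpa(rng), random_tpa(rng)
        w = WeightConfig(2, 2, 1, 1)
        assert weighted_distance(edwa(a, b), w) == weighted_distance(edwa(b, a), w)
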