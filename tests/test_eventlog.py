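"""Event-log ingestion, filtering and day segmentation."""

import datetime as dt
import textwrap

import numpy as np
import pytest

from behaviorflow.eventlog import (
    EventLog,
    LocationEvent,
    LogFormatError,
    Visit,
    expand_to_events,
    filter_log,
    read_csv_events,
    read_mxml,
    segment_by_day,
    write_mxml,
)

from conftest import DAY0, make_log, random_log


def ev(hour, minute, area, resident="R1", day=DAY0):
    return LocationEvent(resident, dt.datetime.combine(day, dt.time(hour, minute)), area)


class TestLocationEvent:
    def test_area_whitespace_normalized(self):
        e = LocationEvent("R1", dt.datetime(2024, 1, 1, 9), "  Sala  TV ")
        assert e.area == "Sala TV"

    def test_empty_area_rejected(self):
        with pytest.raises(ValueError):
            LocationEvent("R1", dt.datetime(2024, 1, 1, 9), "   ")

    def test_subsecond_truncated(self):
        e = LocationEvent("R1", dt.datetime(2024, 1, 1, 9, 0, 0, 999999), "A")
        assert e.timestamp.microsecond == 0


class TestSegmentByDay:
    def test_two_events_one_day(self):
        log = segment_by_day([ev(9, 0, "A"), ev(10, 0, "B")])
        (trace,) = log.traces
        assert [(v.area, v.dwell) for v in trace.visits] == [("A", 3600.0), ("B", 0.0)]

    def test_date_boundary_split(self):
        events = [ev(9, 0, "A"), ev(10, 0, "B"), ev(9, 30, "A", day=DAY0 + dt.timedelta(days=1))]
        log = segment_by_day(events)
        assert [len(t.visits) for t in log.traces] == [2, 1]

    def test_same_area_reads_collapse(self):
        log = segment_by_day([ev(9, 0, "A"), ev(9, 10, "A"), ev(9, 30, "B")])
        (trace,) = log.traces
        assert [(v.area, v.dwell) for v in trace.visits] == [("A", 1800.0), ("B", 0.0)]

    def test_extend_to_midnight_splits_overnight_stay(self):
        day2 = DAY0 + dt.timedelta(days=1)
        events = [ev(22, 0, "A"), ev(1, 0, "A", day=day2), ev(2, 0, "B", day=day2)]
        log = segment_by_day(events, extend_to_midnight=True)
        first, second = log.traces
        assert first.visits[-1].end == dt.datetime.combine(day2, dt.time.min)
        assert second.visits[0].start == dt.datetime.combine(day2, dt.time.min)
        assert second.visits[0].area == "A"

    def test_idempotent_on_expansion(self):
        rng = np.random.default_rng(7)
        log = random_log(rng, 10)
        events = [e for t in log.traces for e in expand_to_events(t)]
        again = segment_by_day(events)
        assert [t.visits for t in again.traces] == [t.visits for t in log.traces]

    def test_residents_kept_apart(self):
        log = segment_by_day([ev(9, 0, "A"), ev(9, 0, "B", resident="R2")])
        assert {(t.resident_id, t.areas) for t in log.traces} == {
            ("R1", ("A",)),
            ("R2", ("B",)),
        }


class TestFilterLog:
    def test_identity_without_criteria(self, branching_log):
        assert filter_log(branching_log).traces == branching_log.traces

    def test_absent_resident_empty(self, branching_log):
        assert len(filter_log(branching_log, resident_id="nobody")) == 0

    def test_closed_date_window_matches_brute_force(self):
        rng = np.random.default_rng(3)
        log = random_log(rng, 25 * 7)
        start = DAY0 + dt.timedelta(days=14)
        end = DAY0 + dt.timedelta(days=20)
        got = filter_log(log, date_start=start, date_end=end)
        expected = [t for t in log.traces if start <= t.day <= end]
        assert got.traces == expected
        assert len(got) == 7

    def test_composition(self):
        rng = np.random.default_rng(4)
        log = random_log(rng, 30)
        c1 = dict(date_start=DAY0 + dt.timedelta(days=5))
        c2 = dict(date_end=DAY0 + dt.timedelta(days=15))
        twice = filter_log(filter_log(log, **c1), **c2)
        once = filter_log(log, **c1, **c2)
        assert twice.traces == once.traces

    def test_inverted_window_rejected(self, branching_log):
        with pytest.raises(ValueError):
            filter_log(branching_log, date_start=dt.date(2024, 2, 1), date_end=DAY0)


class TestMxml:
    def test_single_instance_structure(self, tmp_path):
        content = textwrap.dedent("""\
            <WorkflowLog><Process id="p">
              <ProcessInstance id="R1_2024-01-01">
                <AuditTrailEntry>
                  <WorkflowModelElement>SalaTV</WorkflowModelElement>
                  <EventType>complete</EventType>
                  <Timestamp>2024-01-01T09:00:00</Timestamp>
                </AuditTrailEntry>
                <AuditTrailEntry>
                  <WorkflowModelElement>Comedor</WorkflowModelElement>
                  <Timestamp>2024-01-01T10:00:00</Timestamp>
                </AuditTrailEntry>
                <AuditTrailEntry>
                  <WorkflowModelElement>patio1</WorkflowModelElement>
                  <EventType>schedule</EventType>
                  <Timestamp>2024-01-01T11:00:00</Timestamp>
                </AuditTrailEntry>
              </ProcessInstance>
            </Process></WorkflowLog>
        """)
        path = tmp_path / "log.mxml"
        path.write_text(content)
        log = read_mxml(path)
        (trace,) = log.traces
        # the schedule entry is lifecycle noise and is dropped
        assert trace.areas == ("SalaTV", "Comedor")
        assert trace.resident_id == "R1"
        assert log.metadata["events_dropped_by_type"] == 1

    def test_empty_log_is_valid(self, tmp_path):
        path = tmp_path / "empty.mxml"
        path.write_text("<WorkflowLog><Process id='p'/></WorkflowLog>")
        assert len(read_mxml(path)) == 0

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "bad.mxml"
        path.write_text("<WorkflowLog>\n<oops\n")
        with pytest.raises(LogFormatError, match="line"):
            read_mxml(path)

    def test_missing_timestamp_names_instance(self, tmp_path):
        path = tmp_path / "nots.mxml"
        path.write_text(
            "<WorkflowLog><Process id='p'><ProcessInstance id='R9_x'>"
            "<AuditTrailEntry><WorkflowModelElement>A</WorkflowModelElement>"
            "</AuditTrailEntry></ProcessInstance></Process></WorkflowLog>"
        )
        with pytest.raises(LogFormatError, match="R9_x"):
            read_mxml(path)

    def test_write_then_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        log = random_log(rng, 50)
        path = tmp_path / "rt.mxml"
        write_mxml(log, path)
        back = read_mxml(path)
        assert len(back) == len(log)
        for a, b in zip(log.traces, back.traces):
            assert (a.resident_id, a.day, a.visits) == (b.resident_id, b.day, b.visits)

    def test_write_empty_log(self, tmp_path):
        path = tmp_path / "e.mxml"
        write_mxml(EventLog(), path)
        assert len(read_mxml(path)) == 0


class TestCsv:
    def test_rows_sorted_and_lossless(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text(
            "resident_id,timestamp,area\n"
            "R1,2024-01-01T10:00:00,Comedor\n"
            "R1,2024-01-01T09:00:00,SalaTV\n"
            "R2,2024-01-01T08:00:00,patio1\n"
        )
        events = read_csv_events(path)
        assert [(e.resident_id, e.area) for e in events] == [
            ("R1", "SalaTV"),
            ("R1", "Comedor"),
            ("R2", "patio1"),
        ]

    def test_bad_timestamp_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = ["resident_id,timestamp,area"]
        rows += [f"R1,2024-01-01T0{i}:00:00,A" for i in range(5)]
        rows += ["R1,not-a-time,B", "R1,2024-01-01T07:00:00,A"]
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(LogFormatError, match="row 7"):
            read_csv_events(path)


def test_duplicate_resident_day_rejected():
    t = make_log([["SalaTV"]]).traces[0]
    with pytest.raises(ValueError, match="duplicate"):
        EventLog(traces=[t, t])


def test_visit_invariants():
    with pytest.raises(ValueError):
        Visit("A", dt.datetime(2024, 1, 1, 9), -1.0)
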