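"""Workflow discovery: infer an annotated automaton from an event log.

Every trace is a day's sequence of area visits.  The inferred model has one
node per distinct area (label-merged), a virtual start node, a transition
for every consecutive visit pair observed, and final flags on every area at
which some day ended.  Counts and accumulated dwell are exact tallies over
the log — no frequency threshold is applied, because infrequent movements
(the monthly hairdresser visit) are precisely what behavior-change analysis
must keep.  By construction every training trace replays successfully
against the inferred model.
"""

from __future__ import annotations

from behaviorflow.eventlog import EventLog, Trace
from behaviorflow.tpa import START, TPA

__all__ = ["infer_tpa", "annotate_statistics"]


def infer_tpa(log: EventLog, min_transition_count: int = 0) -> TPA:
    """Infer a frequency- and duration-annotated automaton from *log*.

    Parameters
    ----------
    log:
        Non-empty day-segmented event log.
    min_transition_count:
        Optional post-hoc pruning threshold; transitions observed fewer
        times are dropped *after* inference.  The default 0 keeps every
        observed path, however rare.
    """
    if not log.traces:
        raise ValueError("cannot infer from empty log")
    tpa = TPA()
    tpa.add_node(START)
    for trace in log.traces:
        if not trace.visits:
            raise ValueError(
                f"trace ({trace.resident_id}, {trace.day}) has no visits"
            )
        previous = START
        for visit in trace.visits:
            node = tpa.add_node(visit.area)
            node.visit_count += 1
            node.accumulated_duration += visit.dwell
            tpa.bump_transition(previous, visit.area)
            previous = visit.area
        tpa.final_states.add(previous)
    tpa.training_trace_count = len(log.traces)
    if min_transition_count > 0:
        tpa.transitions = {
            k: t
            for k, t in tpa.transitions.items()
            if t.count >= min_transition_count or START in t.source_nodes
        }
    return tpa


def annotate_statistics(tpa: TPA, log: EventLog) -> TPA:
    """Re-derive all counts and durations of *tpa* from *log*.

    The structure (nodes, transitions, finals) is kept as-is; only the
    annotations are recomputed, which re-grounds a hand-edited model in
    data.  Every trace must conform to the structure.
    """
    out = tpa.structure_only()
    out.final_states = set(tpa.final_states)
    for trace in log.traces:
        previous = out.initial_state
        for i, visit in enumerate(trace.visits):
            if visit.area not in out.nodes or not out.has_transition(previous, visit.area):
                raise ValueError(
                    f"trace ({trace.resident_id}, {trace.day}) does not conform: "
                    f"visit {i} ({previous!r} -> {visit.area!r}) has no match in the model"
                )
            node = out.nodes[visit.area]
            node.visit_count += 1
            node.accumulated_duration += visit.dwell
            out.bump_transition(previous, visit.area)
            previous = visit.area
        if previous not in out.final_states:
            raise ValueError(
                f"trace ({trace.resident_id}, {trace.day}) does not conform: "
                f"ends at non-final {previous!r}"
            )
    out.training_trace_count = len(log.traces)
    return out
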