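"""Model comparison: structural edit distance, trace replay, drift curves.

Two complementary comparisons drive the behavior-change analyses:

* :func:`edwa` — the structural edit distance between two inferred models,
  expressed as four lists: nodes added, nodes deleted, transitions added,
  transitions deleted.  The scalar distance is the weighted count

      WD = w_na*|N_A| + w_nd*|N_D| + w_ta*|T_A| + w_td*|T_D|

  with node differences weighted double the transition differences by
  default (2:1), reflecting that gaining or losing a whole location is a
  bigger behavioral shift than a new path between known locations.

* :func:`wiaa` — replay of one day (a single trace) against a model.  The
  day is accepted when every step fires an existing transition and it ends
  in a final state; otherwise the missing elements that would make it
  conform are reported, and their weighted count is the day's outlier
  score.

On top of these sit the two longitudinal analyses: a per-day outlier
series (each day scored against the previous period's model — sudden
changes show up as isolated peaks) and weekly drift curves (each week's
model compared against week 1 and against the previous week — incremental
drift shows as a growing absolute curve over a flat week-to-week curve).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Optional

from behaviorflow.eventlog import EventLog, Trace
from behaviorflow.inference import infer_tpa
from behaviorflow.tpa import END, START, TPA

__all__ = [
    "DifferenceSet",
    "WeightConfig",
    "ConformanceResult",
    "DriftSeries",
    "edwa",
    "weighted_distance",
    "wiaa",
    "daily_outlier_series",
    "weekly_drift_curves",
]

TransitionKey = tuple[str, str]


@dataclass
class DifferenceSet:
    """The four edit lists of a model comparison.

    ``added_*`` elements exist in the first operand only, ``deleted_*`` in
    the second only.  Transition keys are (source label, target label); a
    target of ``_END_`` encodes "this node must be made final".
    """

    added_nodes: list[str] = field(default_factory=list)
    deleted_nodes: list[str] = field(default_factory=list)
    added_transitions: list[TransitionKey] = field(default_factory=list)
    deleted_transitions: list[TransitionKey] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.added_nodes
            or self.deleted_nodes
            or self.added_transitions
            or self.deleted_transitions
        )

    def __len__(self) -> int:
        return (
            len(self.added_nodes)
            + len(self.deleted_nodes)
            + len(self.added_transitions)
            + len(self.deleted_transitions)
        )


@dataclass(frozen=True)
class WeightConfig:
    """Correction weights of the four difference types.

    The default weighs a node difference twice a transition difference
    (2, 2, 1, 1).
    """

    w_na: float = 2.0
    w_nd: float = 2.0
    w_ta: float = 1.0
    w_td: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_na", "w_nd", "w_ta", "w_td"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


DEFAULT_WEIGHTS = WeightConfig()


@dataclass
class ConformanceResult:
    """Outcome of replaying one day against a model."""

    accepted: bool
    differences: DifferenceSet
    distance: float

    def __post_init__(self) -> None:
        if self.accepted and (not self.differences.is_empty() or self.distance != 0):
            raise ValueError("accepted result must carry no differences")


@dataclass
class DriftSeries:
    """A period-indexed sequence of non-negative model distances."""

    labels: list[str]
    values: list[float]
    mode: str  # "absolute-to-baseline" | "relative-to-previous" | "daily-outlier"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values differ in length")
        if any(v < 0 for v in self.values):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def argmax_label(self) -> Optional[str]:
        """Label of the largest value; ties break to the earliest period."""
        if not self.values:
            return None
        best = max(self.values)
        for label, v in zip(self.labels, self.values):
            if v == best:
                return label
        return None


# ---------------------------------------------------------------------------
# EDWA
# ---------------------------------------------------------------------------

def _node_labels(tpa: TPA) -> set[str]:
    return {label for label in tpa.nodes if label != tpa.initial_state}


def _transition_keys(tpa: TPA) -> set[TransitionKey]:
    keys: set[TransitionKey] = set()
    for t in tpa.transitions.values():
        src = t.source if len(t.source_nodes) == 1 else "|".join(sorted(t.source_nodes))
        # normalize the virtual start label across models
        if src == tpa.initial_state:
            src = START
        keys.add((src, t.target_node))
    return keys


def edwa(tpa1: TPA, tpa2: TPA) -> DifferenceSet:
    """Structural differences of *tpa1* with respect to *tpa2*.

    Elements of *tpa1* missing from *tpa2* are *added*; elements of *tpa2*
    missing from *tpa1* are *deleted*.  Node identity is the area label
    (the virtual start is excluded); transition identity is the
    (source, target) label pair, start transitions included.  Counts play
    no role — the comparison is purely structural.
    """
    n1, n2 = _node_labels(tpa1), _node_labels(tpa2)
    t1, t2 = _transition_keys(tpa1), _transition_keys(tpa2)
    return DifferenceSet(
        added_nodes=sorted(n1 - n2),
        deleted_nodes=sorted(n2 - n1),
        added_transitions=sorted(t1 - t2),
        deleted_transitions=sorted(t2 - t1),
    )


def weighted_distance(
    diffs: DifferenceSet, weights: WeightConfig = DEFAULT_WEIGHTS
) -> float:
    """WD = w_na*|N_A| + w_nd*|N_D| + w_ta*|T_A| + w_td*|T_D|."""
    return (
        weights.w_na * len(diffs.added_nodes)
        + weights.w_nd * len(diffs.deleted_nodes)
        + weights.w_ta * len(diffs.added_transitions)
        + weights.w_td * len(diffs.deleted_transitions)
    )


# ---------------------------------------------------------------------------
# WIAA
# ---------------------------------------------------------------------------

def wiaa(
    tpa: TPA, trace: Trace, weights: WeightConfig = DEFAULT_WEIGHTS
) -> ConformanceResult:
    """Replay one day's area sequence against the model.

    Starting at the virtual start state, each visit must fire a transition
    from the current state to its area; the day must end in a final state.
    On any failure the replay resumes greedily at the node of the next
    area, and the elements the model lacks are recorded:

    * an area absent from the model → an added node, plus the added
      transition that reaches it;
    * a known area with no transition from the current state → an added
      transition;
    * a known, non-final terminal area → an added finality marker,
      recorded as a transition to the ``_END_`` pseudo-target (an added
      node is implicitly final, so ghost terminals add nothing).

    The outlier score is the weighted count of these differences.
    """
    if not trace.visits:
        raise ValueError("cannot replay an empty trace")
    added_nodes: list[str] = []
    added_transitions: list[TransitionKey] = []
    current = tpa.initial_state
    current_is_ghost = False
    for visit in trace.visits:
        area = visit.area
        source = START if current == tpa.initial_state else current
        if area not in tpa.nodes:
            if area not in added_nodes:
                added_nodes.append(area)
            if (source, area) not in added_transitions:
                added_transitions.append((source, area))
            current, current_is_ghost = area, True
        elif not current_is_ghost and tpa.has_transition(current, area):
            current, current_is_ghost = area, False
        else:
            if (source, area) not in added_transitions:
                added_transitions.append((source, area))
            current, current_is_ghost = area, False
    if not current_is_ghost and current not in tpa.final_states:
        added_transitions.append((current, END))
    diffs = DifferenceSet(
        added_nodes=added_nodes, added_transitions=added_transitions
    )
    accepted = diffs.is_empty()
    return ConformanceResult(
        accepted=accepted,
        differences=diffs,
        distance=weighted_distance(diffs, weights),
    )


# ---------------------------------------------------------------------------
# Longitudinal analyses
# ---------------------------------------------------------------------------

def daily_outlier_series(
    model_log: EventLog,
    eval_log: EventLog,
    weights: WeightConfig = DEFAULT_WEIGHTS,
) -> DriftSeries:
    """Score each day of *eval_log* against the model of *model_log*.

    One model is inferred from the whole *model_log* (typically the
    previous month); every trace of *eval_log* is replayed against it and
    its weighted difference count recorded.  Isolated peaks in the
    returned day-indexed series are candidate sudden behavior changes.
    """
    model_range = model_log.date_range
    eval_range = eval_log.date_range
    if model_range and eval_range and model_range[1] >= eval_range[0]:
        warnings.warn(
            "model period does not strictly precede evaluation period "
            f"({model_range[1]} >= {eval_range[0]})",
            stacklevel=2,
        )
    model = infer_tpa(model_log)
    traces = sorted(eval_log.traces, key=lambda t: (t.day, t.resident_id))
    labels = [t.day.isoformat() for t in traces]
    values = [wiaa(model, t, weights).distance for t in traces]
    return DriftSeries(
        labels=labels,
        values=values,
        mode="daily-outlier",
        metadata={
            "model_traces": len(model_log.traces),
            "weights": (weights.w_na, weights.w_nd, weights.w_ta, weights.w_td),
        },
    )


def _iso_week_label(day) -> str:
    year, week, _ = day.isocalendar()
    return f"{year}-W{week:02d}"


def weekly_drift_curves(
    log: EventLog, weights: WeightConfig = DEFAULT_WEIGHTS
) -> tuple[DriftSeries, DriftSeries]:
    """Weekly behavior-change curves over a multi-week log.

    One model is inferred per ISO week (weeks with no traces are skipped
    and flagged in the metadata).  The *absolute* curve compares each
    week's model with the first week's; the *relative* curve (the change
    velocity) compares each week with the preceding observed week.  For a
    stationary routine both stay flat; incremental drift shows as a
    growing absolute curve over a roughly constant relative curve.
    """
    by_week: dict[str, list[Trace]] = {}
    for trace in log.traces:
        by_week.setdefault(_iso_week_label(trace.day), []).append(trace)
    week_labels = sorted(by_week)
    if len(week_labels) < 2:
        raise ValueError("log must span at least two ISO weeks")
    models = {
        w: infer_tpa(EventLog(traces=by_week[w])) for w in week_labels
    }
    baseline = models[week_labels[0]]
    abs_labels, abs_values = [], []
    rel_labels, rel_values = [], []
    for prev, cur in zip(week_labels, week_labels[1:]):
        abs_labels.append(cur)
        abs_values.append(weighted_distance(edwa(models[cur], baseline), weights))
        rel_labels.append(cur)
        rel_values.append(weighted_distance(edwa(models[cur], models[prev]), weights))
    meta = {
        "baseline_week": week_labels[0],
        "weeks": week_labels,
        "skipped_weeks": [],  # weeks absent from the log never appear at all
        "weights": (weights.w_na, weights.w_nd, weights.w_ta, weights.w_td),
    }
    observed = set(by_week)
    # flag calendar weeks inside the span that contributed no traces
    all_days = sorted(t.day for t in log.traces)
    d = all_days[0]
    while d <= all_days[-1]:
        w = _iso_week_label(d)
        if w not in observed and w not in meta["skipped_weeks"]:
            meta["skipped_weeks"].append(w)
        d += dt.timedelta(days=7)
    absolute = DriftSeries(abs_labels, abs_values, "absolute-to-baseline", dict(meta))
    relative = DriftSeries(rel_labels, rel_values, "relative-to-previous", dict(meta))
    return absolute, relative
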