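"""The annotated workflow automaton (TPA) and its DOT/JSON serialization.

A TPA here is a finite automaton over location areas: one node per area,
annotated with how often the area was visited and how long the resident
stayed in it in total, plus counted transitions between areas.  A virtual
start node marks where each day begins; areas at which at least one day
ended are flagged final.  The formalism admits multi-source transitions
(parallel joins); location streams are strictly sequential, so inference
only ever produces single-source transitions.

DOT output is deterministic (elements sorted by label) and can be decorated
with a heat map (white-to-red fill gradient) and/or a difference set from a
model comparison (deleted elements dashed red, added elements bold green —
the convention used to flag, for example, a TV room a resident stopped
visiting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from behaviorflow.compare import DifferenceSet
    from behaviorflow.heatmap import HeatMap

__all__ = [
    "START",
    "END",
    "TPANode",
    "TPATransition",
    "TPA",
    "validate",
    "to_dot",
    "to_json",
    "from_json",
]

#: Label of the virtual start node; excluded from node-level comparisons.
START = "_START_"
#: Pseudo-target used to express "made final" differences in trace replay.
END = "_END_"


@dataclass
class TPANode:
    """An area with its visit count and accumulated dwell (seconds)."""

    label: str
    visit_count: int = 0
    accumulated_duration: float = 0.0

    @property
    def id(self) -> str:
        return self.label


@dataclass(frozen=True)
class TPATransition:
    """A counted state change; ``source_nodes`` is a set to admit parallel
    joins, a singleton for everything inferred from location streams."""

    source_nodes: frozenset[str]
    target_node: str
    count: int = 0

    @property
    def key(self) -> tuple[tuple[str, ...], str]:
        return (tuple(sorted(self.source_nodes)), self.target_node)

    @property
    def source(self) -> str:
        """The single source label (raises for multi-source transitions)."""
        (only,) = self.source_nodes
        return only


@dataclass
class TPA:
    """Annotated workflow automaton over areas."""

    nodes: dict[str, TPANode] = field(default_factory=dict)
    transitions: dict[tuple[tuple[str, ...], str], TPATransition] = field(
        default_factory=dict
    )
    final_states: set[str] = field(default_factory=set)
    training_trace_count: int = 0
    initial_state: str = START

    def add_node(self, label: str) -> TPANode:
        if label not in self.nodes:
            self.nodes[label] = TPANode(label)
        return self.nodes[label]

    def add_transition(self, source: str, target: str, count: int = 0) -> TPATransition:
        key = ((source,), target)
        if key not in self.transitions:
            self.transitions[key] = TPATransition(frozenset({source}), target, count)
        return self.transitions[key]

    def bump_transition(self, source: str, target: str, by: int = 1) -> None:
        key = ((source,), target)
        t = self.transitions.get(key)
        if t is None:
            self.transitions[key] = TPATransition(frozenset({source}), target, by)
        else:
            self.transitions[key] = TPATransition(t.source_nodes, t.target_node, t.count + by)

    def has_transition(self, source: str, target: str) -> bool:
        return ((source,), target) in self.transitions

    @property
    def area_nodes(self) -> list[TPANode]:
        """Real area nodes, excluding the virtual start."""
        return [n for label, n in self.nodes.items() if label != START]

    def structure_only(self) -> "TPA":
        """Copy with all counts and durations zeroed (structure preserved)."""
        out = TPA(
            final_states=set(self.final_states),
            training_trace_count=0,
            initial_state=self.initial_state,
        )
        for label in self.nodes:
            out.add_node(label)
        for t in self.transitions.values():
            out.transitions[t.key] = TPATransition(t.source_nodes, t.target_node, 0)
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for label, node in self.nodes.items():
            g.add_node(
                label,
                visit_count=node.visit_count,
                accumulated_duration=node.accumulated_duration,
            )
        for t in self.transitions.values():
            for src in t.source_nodes:
                g.add_edge(src, t.target_node, count=t.count)
        return g


def validate(tpa: TPA) -> list[str]:
    """Check all automaton invariants; return one message per violation."""
    problems: list[str] = []
    for label, node in tpa.nodes.items():
        if node.visit_count < 0:
            problems.append(f"node {label!r}: negative visit_count {node.visit_count}")
        if node.accumulated_duration < 0:
            problems.append(
                f"node {label!r}: negative accumulated_duration "
                f"{node.accumulated_duration}"
            )
        if node.visit_count == 0 and node.accumulated_duration > 0 and label != START:
            problems.append(
                f"node {label!r}: accumulated_duration without any visit"
            )
    for t in tpa.transitions.values():
        if not t.source_nodes:
            problems.append(f"transition into {t.target_node!r}: empty source set")
        for src in t.source_nodes:
            if src not in tpa.nodes:
                problems.append(
                    f"transition {src!r}->{t.target_node!r}: unknown source {src!r}"
                )
        if t.target_node not in tpa.nodes:
            problems.append(
                f"transition into {t.target_node!r}: unknown target {t.target_node!r}"
            )
        if t.count < 0:
            problems.append(
                f"transition into {t.target_node!r}: negative count {t.count}"
            )
    for label in tpa.final_states:
        if label not in tpa.nodes:
            problems.append(f"final state {label!r} is not a node")
    if tpa.initial_state in tpa.nodes or tpa.transitions:
        g = tpa.to_networkx()
        g.add_node(tpa.initial_state)
        reachable = nx.descendants(g, tpa.initial_state) | {tpa.initial_state}
        for label in tpa.nodes:
            if label not in reachable:
                problems.append(f"node {label!r} unreachable from the initial state")
    start_out = sum(
        t.count for t in tpa.transitions.values() if tpa.initial_state in t.source_nodes
    )
    if tpa.training_trace_count and start_out != tpa.training_trace_count:
        problems.append(
            f"start transitions carry count {start_out}, expected "
            f"training_trace_count {tpa.training_trace_count}"
        )
    return problems


# ---------------------------------------------------------------------------
# DOT
# ---------------------------------------------------------------------------

def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _quote(s: str) -> str:
    return '"' + _escape(s) + '"'


def _heat_color(intensity: float) -> str:
    # white -> red linear gradient
    level = max(0.0, min(1.0, intensity))
    other = round(255 * (1.0 - level))
    return f"#ff{other:02x}{other:02x}"


def _fmt_duration(seconds: float) -> str:
    seconds = int(round(seconds))
    h, rem = divmod(seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h:d}:{m:02d}:{s:02d}"


def to_dot(
    tpa: TPA,
    heatmap: Optional["HeatMap"] = None,
    differences: Optional["DifferenceSet"] = None,
) -> str:
    """Render the automaton as deterministic DOT text.

    Node labels show the area, visit count and accumulated stay.  With a
    heat map, fill colors follow a white-to-red gradient.  With a
    difference set, deleted elements (present in the reference only) are
    drawn dashed red — as ghosts if absent from *tpa* — and added elements
    bold green.
    """
    added_nodes: set[str] = set()
    deleted_nodes: set[str] = set()
    added_edges: set[tuple[str, str]] = set()
    deleted_edges: set[tuple[str, str]] = set()
    if differences is not None:
        added_nodes = set(differences.added_nodes)
        deleted_nodes = set(differences.deleted_nodes)
        added_edges = {(t[0], t[1]) for t in differences.added_transitions}
        deleted_edges = {(t[0], t[1]) for t in differences.deleted_transitions}

    lines = ["digraph behaviorflow {", "  rankdir=LR;", '  node [shape=box, style="rounded,filled", fillcolor=white];']
    lines.append(f"  {_quote(tpa.initial_state)} [shape=point, label=\"\"];")

    all_node_labels = sorted(set(tpa.nodes) - {tpa.initial_state} | deleted_nodes | added_nodes)
    for label in all_node_labels:
        node = tpa.nodes.get(label)
        attrs = []
        if node is not None:
            # \n is DOT's in-label line break and must survive quoting
            text = (
                f"{_escape(label)}\\nvisits={node.visit_count}"
                f"\\nstay={_fmt_duration(node.accumulated_duration)}"
            )
        else:
            text = _escape(label)  # ghost element from a comparison
        attrs.append(f'label="{text}"')
        if heatmap is not None and label in heatmap.node_intensity:
            attrs.append(f'fillcolor="{_heat_color(heatmap.node_intensity[label])}"')
        if label in deleted_nodes:
            attrs.append('color=red')
            attrs.append('fontcolor=red')
            attrs.append('style="rounded,filled,dashed"')
        elif label in added_nodes:
            attrs.append('color=green')
            attrs.append('style="rounded,filled,bold"')
        if label in tpa.final_states:
            attrs.append("peripheries=2")
        lines.append(f"  {_quote(label)} [{', '.join(attrs)}];")

    edge_pairs: dict[tuple[str, str], Optional[TPATransition]] = {}
    for t in tpa.transitions.values():
        for src in sorted(t.source_nodes):
            edge_pairs[(src, t.target_node)] = t
    for pair in added_edges | deleted_edges:
        edge_pairs.setdefault(pair, None)
    for (src, dst) in sorted(edge_pairs):
        t = edge_pairs[(src, dst)]
        attrs = []
        if t is not None:
            attrs.append(f'label="{t.count}"')
        if heatmap is not None and (src, dst) in heatmap.transition_intensity:
            attrs.append(f'color="{_heat_color(heatmap.transition_intensity[(src, dst)])}"')
        if (src, dst) in deleted_edges:
            attrs.append("color=red")
            attrs.append("style=dashed")
        elif (src, dst) in added_edges:
            attrs.append("color=green")
            attrs.append("style=bold")
        attr_text = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(src)} -> {_quote(dst)}{attr_text};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def to_json(tpa: TPA, path: Optional[str | Path] = None) -> str:
    """Serialize to the documented JSON schema; optionally write to *path*."""
    doc = {
        "format": "behaviorflow-tpa",
        "version": 1,
        "initial_state": tpa.initial_state,
        "training_trace_count": tpa.training_trace_count,
        "nodes": [
            {
                "label": n.label,
                "visit_count": n.visit_count,
                "accumulated_duration": n.accumulated_duration,
                "final": n.label in tpa.final_states,
            }
            for n in sorted(tpa.nodes.values(), key=lambda n: n.label)
        ],
        "transitions": [
            {
                "source_nodes": sorted(t.source_nodes),
                "target": t.target_node,
                "count": t.count,
            }
            for t in sorted(tpa.transitions.values(), key=lambda t: t.key)
        ],
    }
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source: str | Path) -> TPA:
    """Load a TPA written by :func:`to_json` (a path or raw JSON text)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = json.loads(text)
    if doc.get("format") != "behaviorflow-tpa":
        raise ValueError("not a behaviorflow TPA document")
    tpa = TPA(
        initial_state=doc.get("initial_state", START),
        training_trace_count=doc.get("training_trace_count", 0),
    )
    for n in doc["nodes"]:
        node = tpa.add_node(n["label"])
        node.visit_count = int(n["visit_count"])
        node.accumulated_duration = float(n["accumulated_duration"])
        if n.get("final"):
            tpa.final_states.add(n["label"])
    for t in doc["transitions"]:
        sources = frozenset(t["source_nodes"])
        tr = TPATransition(sources, t["target"], int(t["count"]))
        tpa.transitions[tr.key] = tr
    return tpa
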