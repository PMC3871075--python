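"""Heat-map intensities and the favorite-areas duration analysis.

A model says *where* a resident goes; the heat map says where they *live*:
node intensity is the area's accumulated dwell normalized by the maximum
over the model, transition intensity the analogous count ratio, both in
[0, 1].  An optional threshold suppresses (zeroes) everything below it so
only the strong flows stay highlighted.  The favorite-areas table tracks
per-period total stay in each area over weeks or months — the seasonal
indoor/outdoor shift of a resident is the canonical pattern it surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from behaviorflow.eventlog import EventLog
from behaviorflow.tpa import TPA

__all__ = ["HeatMap", "AreaDurationTable", "hmra", "favorite_areas"]


@dataclass
class HeatMap:
    """Normalized highlight intensities for a model's nodes and transitions."""

    node_intensity: dict[str, float] = field(default_factory=dict)
    transition_intensity: dict[tuple[str, str], float] = field(default_factory=dict)
    node_metric: str = "accumulated_duration"
    transition_metric: str = "count"
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        for label, v in self.node_intensity.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"node intensity {v} for {label!r} outside [0, 1]")
        for key, v in self.transition_intensity.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"transition intensity {v} for {key} outside [0, 1]")


@dataclass
class AreaDurationTable:
    """Per-period accumulated stay per area, as a tidy DataFrame."""

    frame: pd.DataFrame  # columns: period, area, dwell_seconds
    period: str  # "week" | "month"
    favorites: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _normalize(values: dict, threshold: Optional[float]) -> dict:
    if not values:
        return {}
    peak = max(values.values())
    if peak <= 0:
        # all-equal degenerate case: everything is maximal
        out = {k: 1.0 for k in values}
    else:
        out = {k: v / peak for k, v in values.items()}
    if threshold is not None:
        out = {k: (v if v >= threshold else 0.0) for k, v in out.items()}
    return out


def hmra(tpa: TPA, threshold: Optional[float] = None) -> HeatMap:
    """Compute highlight intensities for *tpa*.

    Node intensity = accumulated dwell / maximum accumulated dwell;
    transition intensity = count / maximum count.  With a *threshold*,
    intensities below it are zeroed (suppressed from highlighting).  An
    empty model yields an empty map.
    """
    durations = {
        n.label: float(n.accumulated_duration)
        for n in tpa.area_nodes
    }
    counts: dict[tuple[str, str], float] = {}
    for t in tpa.transitions.values():
        for src in t.source_nodes:
            counts[(src, t.target_node)] = float(t.count)
    return HeatMap(
        node_intensity=_normalize(durations, threshold),
        transition_intensity=_normalize(counts, threshold),
        threshold=threshold,
    )


def _period_label(day, period: str) -> str:
    if period == "week":
        year, week, _ = day.isocalendar()
        return f"{year}-W{week:02d}"
    if period == "month":
        return f"{day.year}-{day.month:02d}"
    raise ValueError(f"unknown period {period!r}; use 'week' or 'month'")


def favorite_areas(
    log: EventLog, period: str = "month", top_k: int = 7
) -> AreaDurationTable:
    """Per-period accumulated stay per area, sorted for plotting.

    Rows are ordered by period then descending dwell, so the head of each
    period block is that period's most-lived-in area.  ``favorites`` names
    the *top_k* areas by total dwell over the whole log; the table itself
    is never truncated.  Per period, the area dwells sum exactly to the
    total dwell observed in that period's traces.
    """
    if not log.traces:
        raise ValueError("cannot tabulate an empty log")
    rows = [
        (_period_label(t.day, period), v.area, v.dwell)
        for t in log.traces
        for v in t.visits
    ]
    df = pd.DataFrame(rows, columns=["period", "area", "dwell_seconds"])
    table = (
        df.groupby(["period", "area"], as_index=False)["dwell_seconds"]
        .sum()
        .sort_values(
            ["period", "dwell_seconds", "area"], ascending=[True, False, True]
        )
        .reset_index(drop=True)
    )
    totals = (
        df.groupby("area")["dwell_seconds"].sum().sort_values(ascending=False)
    )
    favorites = list(totals.index[:top_k])
    return AreaDurationTable(frame=table, period=period, favorites=favorites)


def plot_favorite_areas(table: AreaDurationTable, path: str | Path) -> None:
    """Line chart of per-period stay for the favorite areas (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    pivot = table.frame.pivot(index="period", columns="area", values="dwell_seconds")
    for area in table.favorites:
        if area in pivot.columns:
            ax.plot(pivot.index, pivot[area] / 3600.0, marker="o", label=area)
    ax.set_xlabel(table.period)
    ax.set_ylabel("stay (hours)")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
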