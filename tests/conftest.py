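"""Shared fixtures: hand-built traces and random log/model generators."""

from __future__ import annotations

import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for dot_grammar

from behaviorflow.eventlog import EventLog, LocationEvent, Trace, Visit
from behaviorflow.inference import infer_tpa

AREA_POOL = ["SalaTV", "Comedor", "Habitaciones", "biblio", "patio1", "patio2", "patio3"]

DAY0 = dt.date(2024, 1, 1)


def make_trace(
    areas: list[str],
    resident: str = "R1",
    day: dt.date = DAY0,
    dwells: list[float] | None = None,
    start: dt.time = dt.time(8, 0),
) -> Trace:
    """Build a contiguous trace from an area sequence (last dwell 0 unless given)."""
    if dwells is None:
        dwells = [600.0] * (len(areas) - 1) + [0.0]
    visits = []
    t = dt.datetime.combine(day, start)
    for area, dwell in zip(areas, dwells):
        visits.append(Visit(area, t, dwell))
        t += dt.timedelta(seconds=dwell)
    return Trace(resident, day, tuple(visits))


def make_log(area_seqs: list[list[str]], resident: str = "R1") -> EventLog:
    """One trace per sequence, on consecutive days."""
    traces = [
        make_trace(seq, resident, DAY0 + dt.timedelta(days=i))
        for i, seq in enumerate(area_seqs)
    ]
    return EventLog(traces=traces)


def random_area_sequence(rng: np.random.Generator, pool=AREA_POOL) -> list[str]:
    length = int(rng.integers(1, 11))
    seq = [pool[rng.integers(len(pool))]]
    while len(seq) < length:
        nxt = pool[rng.integers(len(pool))]
        if nxt != seq[-1]:
            seq.append(nxt)
    return seq


def random_log(
    rng: np.random.Generator,
    n_traces: int | None = None,
    resident: str = "R1",
) -> EventLog:
    if n_traces is None:
        n_traces = int(rng.integers(5, 51))
    seqs = [random_area_sequence(rng) for _ in range(n_traces)]
    traces = []
    for i, seq in enumerate(seqs):
        dwells = [float(rng.integers(60, 3600)) for _ in seq]
        dwells[-1] = float(rng.integers(0, 3600))
        traces.append(
            make_trace(seq, resident, DAY0 + dt.timedelta(days=i), dwells)
        )
    return EventLog(traces=traces)


def random_tpa(rng: np.random.Generator):
    """A valid random model, obtained by inferring from a random log."""
    return infer_tpa(random_log(rng, int(rng.integers(2, 12))))


@pytest.fixture
def two_visit_log() -> EventLog:
    return make_log([["SalaTV", "Comedor"]])


@pytest.fixture
def branching_log() -> EventLog:
    # {[A,B,C], [A,C]} with A=SalaTV, B=Comedor, C=biblio
    return make_log([["SalaTV", "Comedor", "biblio"], ["SalaTV", "biblio"]])
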