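"""Synthetic resident-movement generator.

Real indoor-location corpora from care facilities are private, so every
analysis here is exercised on simulated residents.  A resident is a
semi-Markov process over a fixed set of areas: each day starts in an area
drawn from a start distribution, dwell times are drawn per area from a
shifted exponential (60 s minimum — a beacon hand-off faster than that is
a read artifact, not a stay; a gamma alternative is available), and the
next area follows a row-stochastic transition matrix with zero diagonal
(an event is a *change* of area).  One event is emitted per area entry,
exactly what a beacon-based location system logs.

Behavior change is injected on top of a baseline profile either *suddenly*
(from an onset date the target profile takes over) or *incrementally* (the
matrices, dwell means and start distribution move along the convex path
toward the target at a fixed per-week rate).  All randomness flows through
one numpy PCG64 generator, so a seed fixes the corpus byte for byte on any
platform.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from behaviorflow.eventlog import EventLog, LocationEvent, segment_by_day

__all__ = [
    "ResidentProfile",
    "ChangeSpec",
    "simulate_resident",
    "apply_change",
    "inject_change_day",
    "nursing_home_profile",
    "winter_profile",
    "sick_day_profile",
]

_ATOL = 1e-9


@dataclass
class ResidentProfile:
    """Stochastic movement profile of one resident.

    Attributes
    ----------
    areas:
        Area labels; indices align with the matrix and vectors below.
    transition_matrix:
        Row-stochastic next-area probabilities, zero diagonal.
    dwell_means:
        Mean stay per area in seconds (each > ``dwell_min``).
    start_distribution:
        Probability of starting the day in each area.
    day_start, day_end:
        Clock times bounding a day's activity.
    dwell_min:
        Hard lower bound on a stay, seconds.
    dwell_model:
        "exponential" (shifted) or "gamma" (shifted, shape ``gamma_shape``).
    """

    areas: list[str]
    transition_matrix: np.ndarray
    dwell_means: np.ndarray
    start_distribution: np.ndarray
    day_start: dt.time = dt.time(8, 0)
    day_end: dt.time = dt.time(21, 0)
    dwell_min: float = 60.0
    dwell_model: str = "exponential"
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.dwell_means = np.asarray(self.dwell_means, dtype=float)
        self.start_distribution = np.asarray(self.start_distribution, dtype=float)

    def validate(self) -> None:
        n = len(self.areas)
        if self.transition_matrix.shape != (n, n):
            raise ValueError(
                f"transition matrix shape {self.transition_matrix.shape} "
                f"does not match {n} areas"
            )
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ATOL):
            raise ValueError(f"transition matrix rows must sum to 1 (got {rows})")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition matrix has negative entries")
        if np.any(np.abs(np.diag(self.transition_matrix)) > _ATOL):
            raise ValueError("transition matrix diagonal must be zero (a move changes area)")
        if not np.isclose(self.start_distribution.sum(), 1.0, atol=_ATOL):
            raise ValueError("start distribution must sum to 1")
        if np.any(self.start_distribution < 0):
            raise ValueError("start distribution has negative entries")
        if np.any(self.dwell_means <= self.dwell_min):
            raise ValueError(f"dwell means must exceed dwell_min={self.dwell_min}")
        if self.dwell_model not in ("exponential", "gamma"):
            raise ValueError(f"unknown dwell model {self.dwell_model!r}")

    def mix(self, other: "ResidentProfile", lam: float) -> "ResidentProfile":
        """Convex combination (1-lam)*self + lam*other of the stochastic
        components; areas and clock bounds come from *self*."""
        if self.areas != other.areas:
            raise ValueError("profiles to mix must share the same area list")
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"mixing coefficient {lam} outside [0, 1]")
        mixed = replace(
            self,
            transition_matrix=(1 - lam) * self.transition_matrix
            + lam * other.transition_matrix,
            dwell_means=(1 - lam) * self.dwell_means + lam * other.dwell_means,
            start_distribution=(1 - lam) * self.start_distribution
            + lam * other.start_distribution,
        )
        return mixed


@dataclass
class ChangeSpec:
    """A behavior change to impose on a baseline profile.

    ``kind="sudden"`` switches to ``target_profile`` from ``onset`` on;
    ``kind="incremental"`` interpolates toward it, the coefficient growing
    by ``rate`` per simulated week (capped at 1).
    """

    kind: str
    target_profile: ResidentProfile
    onset: Optional[dt.date] = None
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sudden", "incremental"):
            raise ValueError(f"unknown change kind {self.kind!r}")
        if self.kind == "sudden" and self.onset is None:
            raise ValueError("sudden change requires an onset date")
        if self.kind == "incremental":
            if self.rate is None or not 0.0 <= self.rate <= 1.0:
                raise ValueError("incremental change requires a rate in [0, 1]")


def _simulate_day(
    profile: ResidentProfile,
    resident_id: str,
    day: dt.date,
    rng: np.random.Generator,
) -> list[LocationEvent]:
    n = len(profile.areas)
    t = dt.datetime.combine(day, profile.day_start)
    end = dt.datetime.combine(day, profile.day_end)
    idx = int(rng.choice(n, p=profile.start_distribution))
    events = [LocationEvent(resident_id, t, profile.areas[idx])]
    while True:
        mean_excess = profile.dwell_means[idx] - profile.dwell_min
        if profile.dwell_model == "gamma":
            dwell = profile.dwell_min + rng.gamma(
                profile.gamma_shape, mean_excess / profile.gamma_shape
            )
        else:
            dwell = profile.dwell_min + rng.exponential(mean_excess)
        t = t + dt.timedelta(seconds=float(dwell))
        if t >= end:
            break
        idx = int(rng.choice(n, p=profile.transition_matrix[idx]))
        events.append(LocationEvent(resident_id, t, profile.areas[idx]))
    return events


def _simulate(
    profile_for_day: Callable[[int, dt.date], ResidentProfile],
    n_days: int,
    seed: int,
    resident_id: str,
    start_date: dt.date,
) -> EventLog:
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    events: list[LocationEvent] = []
    for d in range(n_days):
        day = start_date + dt.timedelta(days=d)
        profile = profile_for_day(d, day)
        profile.validate()
        events.extend(_simulate_day(profile, resident_id, day, rng))
    log = segment_by_day(events)
    log.metadata.update(
        {
            "source": "synthetic",
            "seed": seed,
            "n_days": n_days,
            "resident_id": resident_id,
            "start_date": start_date.isoformat(),
        }
    )
    return log


def simulate_resident(
    profile: ResidentProfile,
    n_days: int,
    seed: int,
    resident_id: str = "R1",
    start_date: dt.date = dt.date(2024, 1, 1),
) -> EventLog:
    """Simulate *n_days* of movement under a fixed profile.

    Returns the day-segmented event log; fully reproducible from *seed*.
    """
    profile.validate()
    return _simulate(lambda d, day: profile, n_days, seed, resident_id, start_date)


def apply_change(
    profile: ResidentProfile,
    change: ChangeSpec,
    n_days: int,
    seed: int,
    resident_id: str = "R1",
    start_date: dt.date = dt.date(2024, 1, 1),
) -> EventLog:
    """Simulate movement with a sudden or incremental behavior change.

    Sudden: days before the onset follow *profile*, days from the onset on
    follow the target.  Incremental: day ``d`` follows the convex mixture
    with coefficient ``min(1, rate * (d // 7))``, i.e. the mixture advances
    once per simulated week.
    """
    profile.validate()
    change.target_profile.validate()
    if change.kind == "sudden":

        def for_day(d: int, day: dt.date) -> ResidentProfile:
            return change.target_profile if day >= change.onset else profile

    else:

        def for_day(d: int, day: dt.date) -> ResidentProfile:
            lam = min(1.0, change.rate * (d // 7))
            return profile.mix(change.target_profile, lam)

    return _simulate(for_day, n_days, seed, resident_id, start_date)


def inject_change_day(
    profile: ResidentProfile,
    change_profile: ResidentProfile,
    n_days: int,
    change_day_index: int,
    seed: int,
    resident_id: str = "R1",
    start_date: dt.date = dt.date(2024, 1, 1),
) -> EventLog:
    """Simulate a baseline period with exactly one anomalous day.

    Day ``change_day_index`` (0-based) follows *change_profile*; every
    other day follows *profile*.  This is the ground-truth construction
    for sudden-outlier detection: the injected index is known, so a
    detector's peak can be scored against it.
    """
    if not 0 <= change_day_index < n_days:
        raise ValueError("change_day_index outside the simulated range")
    profile.validate()
    change_profile.validate()
    return _simulate(
        lambda d, day: change_profile if d == change_day_index else profile,
        n_days,
        seed,
        resident_id,
        start_date,
    )


# ---------------------------------------------------------------------------
# Stock profiles
# ---------------------------------------------------------------------------

AREAS = ["SalaTV", "Comedor", "Habitaciones", "biblio", "patio1", "patio2", "patio3"]


def nursing_home_profile() -> ResidentProfile:
    """Baseline summer routine over the seven stock areas.

    The resident alternates between the TV room, dining room, their own
    room and the library, with regular strolls to the three courtyards.
    Mean stays range from a quarter hour (far courtyard) to an hour and a
    half (own room); days run 08:00-21:00.
    """
    matrix = np.array(
        [
            # SalaTV Comedor Habit  biblio patio1 patio2 patio3
            [0.00, 0.35, 0.25, 0.15, 0.15, 0.05, 0.05],  # SalaTV
            [0.40, 0.00, 0.25, 0.10, 0.15, 0.05, 0.05],  # Comedor
            [0.35, 0.30, 0.00, 0.15, 0.10, 0.05, 0.05],  # Habitaciones
            [0.30, 0.25, 0.25, 0.00, 0.10, 0.05, 0.05],  # biblio
            [0.25, 0.25, 0.20, 0.10, 0.00, 0.15, 0.05],  # patio1
            [0.25, 0.25, 0.20, 0.10, 0.15, 0.00, 0.05],  # patio2
            [0.25, 0.25, 0.20, 0.10, 0.10, 0.10, 0.00],  # patio3
        ]
    )
    return ResidentProfile(
        areas=list(AREAS),
        transition_matrix=matrix,
        dwell_means=np.array([3600.0, 2700.0, 5400.0, 1800.0, 1500.0, 1200.0, 900.0]),
        start_distribution=np.array([0.05, 0.15, 0.60, 0.05, 0.05, 0.05, 0.05]),
    )


def winter_profile() -> ResidentProfile:
    """Indoor-shifted routine over the same areas: courtyards abandoned,
    longer stays in the TV room, dining room and own room.  Used as the
    target of incremental seasonal drift."""
    matrix = np.array(
        [
            [0.00, 0.40, 0.35, 0.25, 0.00, 0.00, 0.00],  # SalaTV
            [0.45, 0.00, 0.30, 0.25, 0.00, 0.00, 0.00],  # Comedor
            [0.40, 0.35, 0.00, 0.25, 0.00, 0.00, 0.00],  # Habitaciones
            [0.40, 0.35, 0.25, 0.00, 0.00, 0.00, 0.00],  # biblio
            [0.40, 0.30, 0.20, 0.10, 0.00, 0.00, 0.00],  # patio1
            [0.40, 0.30, 0.20, 0.10, 0.00, 0.00, 0.00],  # patio2
            [0.40, 0.30, 0.20, 0.10, 0.00, 0.00, 0.00],  # patio3
        ]
    )
    return ResidentProfile(
        areas=list(AREAS),
        transition_matrix=matrix,
        dwell_means=np.array([4800.0, 3000.0, 6600.0, 2400.0, 600.0, 600.0, 600.0]),
        start_distribution=np.array([0.10, 0.20, 0.60, 0.10, 0.00, 0.00, 0.00]),
    )


def sick_day_profile() -> ResidentProfile:
    """An anomalous day: the resident keeps to their room and the
    infirmary, with short trips to the dining room.  Introduces an area
    (Enfermeria) absent from the baseline routine, the signature of a
    sudden outlier day."""
    areas = ["Habitaciones", "Enfermeria", "Comedor"]
    matrix = np.array(
        [
            [0.0, 0.6, 0.4],
            [0.7, 0.0, 0.3],
            [0.8, 0.2, 0.0],
        ]
    )
    return ResidentProfile(
        areas=areas,
        transition_matrix=matrix,
        dwell_means=np.array([9000.0, 3600.0, 1800.0]),
        start_distribution=np.array([0.8, 0.1, 0.1]),
    )
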