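"""Event-log formats, session schedules, validation, and hourly binning.

The canonical on-disk format for entry events is a UTF-8 CSV with header
``animal_id,t_seconds,hole``: one row per hole entry, times in seconds since
session start, hole one of ``left``/``middle``/``right``. In memory, events
are a :class:`pandas.DataFrame` with those columns, sorted by
``(animal_id, t_seconds)``.

A :class:`SessionSchedule` describes the 90-h discrimination/reversal session:
an acquisition phase (correct hole on the left) followed by a reversal phase
(correct hole on the right), under a repeating 12-h light:12-h dark cycle.
Hour windows throughout the package are half-open ``[h, h+1)`` and 0-based
from session start; an event exactly on a phase boundary belongs to the later
phase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOLES = ("left", "middle", "right")
EVENT_COLUMNS = ["animal_id", "t_seconds", "hole"]

ACQUISITION = "acquisition"
REVERSAL = "reversal"


class EventLogError(ValueError):
    """Raised for structurally invalid event logs (bad schema, bad values)."""


@dataclass(frozen=True)
class SessionSchedule:
    """Phase boundaries, correct-hole map, and light:dark timing.

    Parameters
    ----------
    session_hours
        Total session duration in hours (default 90).
    acquisition_end
        First hour of the reversal phase; acquisition is ``[0, acquisition_end)``
        and reversal ``[acquisition_end, session_hours)`` (default 49).
    dark_onset
        Hour of the first dark-phase start (default 3, so dark phases fall at
        [3, 15), [27, 39), [51, 63), [75, 87) hours).
    dark_hours, light_hours
        Durations of the dark and light parts of the cycle (default 12 h each).
    """

    session_hours: int = 90
    acquisition_end: int = 49
    acquisition_hole: str = "left"
    reversal_hole: str = "right"
    dark_onset: int = 3
    dark_hours: int = 12
    light_hours: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.acquisition_end < self.session_hours):
            raise ValueError("acquisition_end must lie strictly inside the session")
        if self.acquisition_hole not in HOLES or self.reversal_hole not in HOLES:
            raise ValueError(f"correct holes must be among {HOLES}")
        if self.dark_hours <= 0 or self.light_hours <= 0:
            raise ValueError("dark_hours and light_hours must be positive")
        if not 0 <= self.dark_onset:
            raise ValueError("dark_onset must be non-negative")

    @property
    def session_seconds(self) -> float:
        return self.session_hours * 3600.0

    def phase_of_hours(self, t_hours):
        """Phase label for time(s) given in hours; vectorized over arrays."""
        return np.where(np.asarray(t_hours) < self.acquisition_end, ACQUISITION, REVERSAL)

    def correct_hole_of_hours(self, t_hours):
        return np.where(
            np.asarray(t_hours) < self.acquisition_end,
            self.acquisition_hole,
            self.reversal_hole,
        )

    def phase_interval(self, phase: str) -> tuple[int, int]:
        """Half-open ``[start, end)`` hour interval of a phase."""
        if phase == ACQUISITION:
            return (0, self.acquisition_end)
        if phase == REVERSAL:
            return (self.acquisition_end, self.session_hours)
        raise ValueError(f"unknown phase {phase!r}")

    def correct_hole(self, phase: str) -> str:
        return self.acquisition_hole if phase == ACQUISITION else self.reversal_hole

    def is_dark_hour(self, hour):
        """True where whole hour index falls in a dark phase; vectorized."""
        cycle = self.dark_hours + self.light_hours
        return (np.asarray(hour) - self.dark_onset) % cycle < self.dark_hours

    def dark_window(self, phase: str, length: int = 10) -> tuple[int, int]:
        """First ``length`` hours of the first dark phase inside ``phase``.

        With the defaults this reproduces the hours-3–12 acquisition window
        ([3, 13)) and the hours-51–61 reversal window ([51, 61)).
        """
        start, end = self.phase_interval(phase)
        cycle = self.dark_hours + self.light_hours
        for h in range(start, end):
            if (h - self.dark_onset) % cycle < self.dark_hours:
                return (h, min(h + length, end))
        raise ValueError(f"no dark hour inside phase {phase!r}")


@dataclass(frozen=True)
class Violation:
    kind: str
    animal_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "event log valid (no violations)"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.kind}] {v.animal_id}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def _require_schema(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventLogError(f"event log missing columns: {missing}")


def read_event_log(path) -> pd.DataFrame:
    """Read an event-log CSV, enforcing schema and per-animal time ordering.

    Returns events grouped by animal and sorted by time. Unknown hole labels
    and non-monotonic timestamps are hard errors naming the offending line or
    animal.
    """
    events = pd.read_csv(path, dtype={"animal_id": str, "hole": str})
    _require_schema(events)
    events = events[EVENT_COLUMNS].copy()
    events["t_seconds"] = pd.to_numeric(events["t_seconds"], errors="coerce")

    bad_hole = ~events["hole"].isin(HOLES)
    if bad_hole.any():
        # +2: one for the header row, one for 0- vs 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad_hole.to_numpy())[:5]]
        label = events.loc[bad_hole, "hole"].iloc[0]
        raise EventLogError(f"unknown hole label {label!r} at line(s) {lines} of {path}")
    bad_t = events["t_seconds"].isna()
    if bad_t.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad_t.to_numpy())[:5]]
        raise EventLogError(f"non-numeric t_seconds at line(s) {lines} of {path}")

    events = events.sort_values(["animal_id", "t_seconds"], kind="mergesort")
    for animal, grp in events.groupby("animal_id", sort=False):
        t = grp["t_seconds"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise EventLogError(
                f"non-monotonic timestamps for animal {animal!r} "
                "(times must be strictly increasing)"
            )
    return events.reset_index(drop=True)


def write_event_log(events: pd.DataFrame, path):
    """Write events as CSV with deterministic (animal, time) ordering."""
    _require_schema(events)
    out = events[EVENT_COLUMNS].sort_values(
        ["animal_id", "t_seconds"], kind="mergesort"
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def validate_event_log(events: pd.DataFrame, schedule: SessionSchedule) -> ValidationReport:
    """Check event-stream invariants against a schedule; never raises.

    Reported violations: times outside ``[0, session_end]``, duplicated or
    decreasing timestamps within an animal, and unknown hole labels.
    """
    report = ValidationReport()
    _require_schema(events)

    bad_hole = ~events["hole"].isin(HOLES)
    for _, row in events.loc[bad_hole].iterrows():
        report.violations.append(
            Violation("unknown_hole", str(row["animal_id"]), f"hole={row['hole']!r}")
        )

    t = events["t_seconds"].to_numpy(dtype=float)
    out_of_range = (t < 0) | (t > schedule.session_seconds)
    for _, row in events.loc[out_of_range].iterrows():
        report.violations.append(
            Violation(
                "time_out_of_range",
                str(row["animal_id"]),
                f"t={row['t_seconds']} outside [0, {schedule.session_seconds}]",
            )
        )

    for animal, grp in events.groupby("animal_id", sort=True):
        tt = grp["t_seconds"].sort_values().to_numpy()
        n_dup = int(np.sum(np.diff(tt) == 0))
        if n_dup:
            report.violations.append(
                Violation("duplicate_time", str(animal), f"{n_dup} duplicated timestamp(s)")
            )
        if len(tt) == 0:
            report.violations.append(Violation("empty_animal", str(animal), "no events"))
    return report


def bin_events_hourly(events: pd.DataFrame, schedule: SessionSchedule) -> pd.DataFrame:
    """Aggregate events to per-animal hourly counts on the full session grid.

    Returns one row per (animal, hour) for every hour 0..session_hours-1 with
    columns ``n_left``/``n_middle``/``n_right``, ``n_correct``/``n_incorrect``/
    ``n_total``, the hour's ``phase`` label and ``is_dark`` flag. Hours without
    events carry zero counts. Correctness is evaluated at the exact event time,
    so an entry at 49.5 h on the left hole counts as incorrect under the
    default schedule (reversal rewards the right hole). An event exactly at
    session end is assigned to the last hour.
    """
    _require_schema(events)
    t_h = events["t_seconds"].to_numpy(dtype=float) / 3600.0
    hour = np.minimum(np.floor(t_h).astype(int), schedule.session_hours - 1)
    correct = events["hole"].to_numpy() == schedule.correct_hole_of_hours(t_h)

    work = pd.DataFrame(
        {
            "animal_id": events["animal_id"].to_numpy(),
            "hour": hour,
            "hole": events["hole"].to_numpy(),
            "correct": correct,
        }
    )
    counts = (
        work.pivot_table(
            index=["animal_id", "hour"],
            columns="hole",
            values="correct",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=list(HOLES), fill_value=0)
        .rename(columns={h: f"n_{h}" for h in HOLES})
    )
    ncorr = work.groupby(["animal_id", "hour"])["correct"].sum().rename("n_correct")

    animals = sorted(events["animal_id"].unique())
    grid = pd.MultiIndex.from_product(
        [animals, range(schedule.session_hours)], names=["animal_id", "hour"]
    )
    bins = counts.join(ncorr).reindex(grid, fill_value=0).reset_index()
    bins["n_correct"] = bins["n_correct"].astype(int)
    bins["n_total"] = bins[["n_left", "n_middle", "n_right"]].sum(axis=1)
    bins["n_incorrect"] = bins["n_total"] - bins["n_correct"]
    bins["phase"] = schedule.phase_of_hours(bins["hour"].to_numpy())
    bins["is_dark"] = schedule.is_dark_hour(bins["hour"].to_numpy())
    return bins[
        [
            "animal_id",
            "hour",
            "n_left",
            "n_middle",
            "n_right",
            "n_correct",
            "n_incorrect",
            "n_total",
            "phase",
            "is_dark",
        ]
    ]


def schedule_to_dict(schedule: SessionSchedule) -> dict:
    return dataclasses.asdict(schedule)


def schedule_from_dict(d: dict) -> SessionSchedule:
    return SessionSchedule(**d)
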