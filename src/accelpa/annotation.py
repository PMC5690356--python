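"""Direct-observation (DO) annotation: activities, intensities, window labels.

The criterion measure is a human-coded stream of timed activity events drawn
from the 13-activity semi-structured protocol.  Each activity maps to a
physical-activity intensity category via Compendium MET values: sedentary
behavior (SB, ≤ 1.5 METs), light (LPA, 1.6–2.9 METs), or moderate-to-vigorous
(MVPA, ≥ 3.0 METs).  Events are projected onto the shared 30-s window grid;
any window containing an activity change or uncovered ("between activities")
time is recoded as TRANSITION, which is bookkeeping only and never a model
output: transition windows are retained for sedentary-break counting but
stripped before classifier training and evaluation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import AnnotationError
from .signal_io import format_iso8601, parse_iso8601

_TIME_EPS = 1e-9  # float-time slop when comparing event/window boundaries


class Activity(str, enum.Enum):
    """The 13 protocol activities (canonical lowercase snake_case names)."""

    LYING_DOWN = "lying_down"
    READING = "reading"
    COMPUTER_USE = "computer_use"
    STANDING = "standing"
    LAUNDRY = "laundry"
    SWEEPING = "sweeping"
    BICEPS_CURLS = "biceps_curls"
    WALKING_SLOW = "walking_slow"
    WALKING_FAST = "walking_fast"
    JOGGING = "jogging"
    CYCLING = "cycling"
    STAIRS = "stairs"
    SQUATS = "squats"


class IntensityCategory(enum.IntEnum):
    """Ordinal PA intensity categories; SB < LPA < MVPA is load-bearing
    (quadratic-weighted kappa penalizes by squared ordinal distance).

    TRANSITION is a bookkeeping value for windows between/across activities;
    it is never a classifier output.
    """

    SB = 0
    LPA = 1
    MVPA = 2
    TRANSITION = 3


def _load_intensity_map() -> dict[Activity, IntensityCategory]:
    with resources.files("accelpa.data").joinpath("activity_intensity.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return {Activity(r["activity"]): IntensityCategory[r["intensity"]] for r in rows}


#: Read-only activity → intensity map, loaded from the shipped data asset.
ACTIVITY_INTENSITY: dict[Activity, IntensityCategory] = _load_intensity_map()

SB_ACTIVITIES = tuple(a for a, c in ACTIVITY_INTENSITY.items() if c == IntensityCategory.SB)


def activity_to_intensity(activity: Activity | str) -> IntensityCategory:
    """Map a protocol activity to its Compendium-based intensity category."""
    try:
        activity = Activity(activity)
    except ValueError as exc:
        raise AnnotationError(f"unknown activity {activity!r}") from exc
    return ACTIVITY_INTENSITY[activity]


@dataclass(frozen=True)
class ActivityEvent:
    """One continuously observed activity bout: [start, end) in POSIX seconds."""

    start: float
    end: float
    activity: Activity

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"event start must precede end ({self.start} >= {self.end})"
            )
        object.__setattr__(self, "activity", Activity(self.activity))


@dataclass(frozen=True)
class WindowLabel:
    """DO label for one 30-s window. ``activity is None`` means TRANSITION."""

    subject_id: str
    window_index: int
    activity: Activity | None
    intensity: IntensityCategory

    @property
    def is_transition(self) -> bool:
        return self.activity is None

    def __post_init__(self) -> None:
        if (self.activity is None) != (self.intensity == IntensityCategory.TRANSITION):
            raise AnnotationError(
                "intensity must be TRANSITION iff activity is TRANSITION"
            )
        if self.activity is not None and (
            ACTIVITY_INTENSITY[Activity(self.activity)] != self.intensity
        ):
            raise AnnotationError(
                f"intensity {self.intensity!r} inconsistent with activity "
                f"{self.activity!r}"
            )


def _check_events(events: Sequence[ActivityEvent]) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.start < prev.start:
            raise AnnotationError("events must be sorted by start time")
        if cur.start < prev.end - _TIME_EPS:
            raise AnnotationError(
                f"overlapping events: {prev.activity.value} "
                f"[{prev.start}, {prev.end}) and {cur.activity.value} "
                f"[{cur.start}, {cur.end})"
            )


def label_windows(
    events: Sequence[ActivityEvent],
    t0: float,
    n_windows: int,
    subject_id: str = "unknown",
    window_s: float = 30.0,
) -> list[WindowLabel]:
    """Project DO events onto the window grid [t0+k·w, t0+(k+1)·w).

    A window wholly covered by a single event receives that event's activity
    and mapped intensity.  A window overlapping two or more events, or
    containing any uncovered time, is recoded TRANSITION — co-occurrence of
    activities and "time between activities" are both transitions.
    Exactly one label per window is returned.
    """
    events = sorted(events, key=lambda e: e.start)
    _check_events(events)
    labels: list[WindowLabel] = []
    for k in range(int(n_windows)):
        w0 = t0 + k * window_s
        w1 = w0 + window_s
        overlapping = [
            e for e in events if e.start < w1 - _TIME_EPS and e.end > w0 + _TIME_EPS
        ]
        if (
            len(overlapping) == 1
            and overlapping[0].start <= w0 + _TIME_EPS
            and overlapping[0].end >= w1 - _TIME_EPS
        ):
            act = overlapping[0].activity
            labels.append(
                WindowLabel(subject_id, k, act, ACTIVITY_INTENSITY[act])
            )
        else:
            labels.append(
                WindowLabel(subject_id, k, None, IntensityCategory.TRANSITION)
            )
    return labels


def strip_transitions(labels: Iterable[WindowLabel]) -> list[WindowLabel]:
    """Drop TRANSITION windows, keeping original window indices (the result
    may be non-contiguous)."""
    return [lab for lab in labels if not lab.is_transition]


# ---------------------------------------------------------------------------
# annotation CSV: subject,start_iso8601,end_iso8601,activity
# ---------------------------------------------------------------------------

def write_annotation_csv(
    events_by_subject: dict[str, Sequence[ActivityEvent]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "start_iso8601", "end_iso8601", "activity"])
        for subject in events_by_subject:
            for e in events_by_subject[subject]:
                writer.writerow(
                    [subject, format_iso8601(e.start), format_iso8601(e.end),
                     e.activity.value]
                )


def read_annotation_csv(path: str | Path) -> dict[str, list[ActivityEvent]]:
    """Read a DO annotation CSV; unknown activity names are rejected outright
    (no fuzzy matching)."""
    out: dict[str, list[ActivityEvent]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"subject", "start_iso8601", "end_iso8601", "activity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AnnotationError(
                f"{path}: annotation CSV must have columns {sorted(required)}"
            )
        for row in reader:
            try:
                act = Activity(row["activity"])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: unknown activity {row['activity']!r}"
                ) from exc
            out.setdefault(row["subject"], []).append(
                ActivityEvent(
                    parse_iso8601(row["start_iso8601"]),
                    parse_iso8601(row["end_iso8601"]),
                    act,
                )
            )
    for events in out.values():
        events.sort(key=lambda e: e.start)
        _check_events(events)
    return out
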