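"""Behavioural event logs for newborn calves.

Continuous focal observations of group-housed calves are coded against an
ethogram in which every behaviour maps to one of four categories:

* ``resting`` — lying (codes ``L``, ``l``)
* ``active``  — standing, posture change, stepping/walking, side-stepping,
  feeding (codes ``S``, ``PC``, ``ST``, ``F``, ``s``, ``t``, ``w``, ``f``)
* ``play``    — locomotor play: running, jumping/hopping, bucking, kicking,
  turning/spinning, leaping (codes ``p``, ``HPF``, ``HPR``, ``LF``, ``LS``,
  ``T``, ``RV``, ``R``, ``BL``, ``BH``, ``BK``, ``K``, and head shakes with
  concurrent limb movement ``HFFM``/``HRFM``)
* ``meta``    — management interventions and out-of-view periods (``M``,
  ``O``); these carry no behavioural information and are excluded from time
  budgets.

All times are seconds from the start of observation.  Events are half-open
intervals ``[start_s, end_s)``; a point event (zero duration) marks presence
at its start second.  Timestamps read from file are truncated to whole
seconds, matching the 1 s synchronisation accuracy of video-coded logs.

A *bout* is a maximal episode of a behaviour: consecutive events of the same
category separated by gaps of at most ``max_gap_s`` (default 1 s — a play
bout ends only when play is discontinued for more than one second) merge
into a single bout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourEvent",
    "EventLog",
    "Bout",
    "TimeBudget",
    "CATEGORY_BY_CODE",
    "BEHAVIOUR_GROUPS",
    "category_for_code",
    "read_event_log",
    "write_event_log",
    "extract_bouts",
    "time_budget",
    "EventLogError",
]

#: Ethogram code -> category.  Head-only head shakes (``HS``) are not leg
#: movement; by default they are excluded from analysis entirely (see
#: :func:`read_event_log`), while the limb-movement variants count as play.
CATEGORY_BY_CODE: dict[str, str] = {
    "L": "resting",
    "l": "resting",
    "S": "active",
    "PC": "active",
    "ST": "active",
    "F": "active",
    "s": "active",
    "t": "active",
    "w": "active",
    "f": "active",
    "p": "play",
    "HFFM": "play",
    "HRFM": "play",
    "HPF": "play",
    "HPR": "play",
    "LF": "play",
    "LS": "play",
    "T": "play",
    "RV": "play",
    "R": "play",
    "BL": "play",
    "BH": "play",
    "BK": "play",
    "K": "play",
    "M": "meta",
    "O": "meta",
}

#: Head-only code excluded by default (no limb movement -> not locomotor play).
HEAD_ONLY_PLAY_CODES = frozenset({"HS"})

CATEGORIES = ("resting", "active", "play", "meta")

#: Behaviour groups reported in time budgets and correlation tables.
BEHAVIOUR_GROUPS: dict[str, frozenset[str]] = {
    "lying": frozenset({"resting"}),
    "play": frozenset({"play"}),
    "active_excl_play": frozenset({"active"}),
    "active_incl_play": frozenset({"active", "play"}),
}


class EventLogError(ValueError):
    """Raised for malformed or inconsistent event-log data."""


def category_for_code(code: str, include_head_only_play: bool = False) -> str:
    """Map an ethogram code to its behavioural category.

    ``HS`` (head shake without concurrent limb movement) is only accepted
    when ``include_head_only_play`` is true, in which case it counts as play.
    """
    if code in HEAD_ONLY_PLAY_CODES:
        if include_head_only_play:
            return "play"
        raise EventLogError(
            f"code {code!r} is head-only play, excluded from locomotor-play analysis"
        )
    try:
        return CATEGORY_BY_CODE[code]
    except KeyError:
        raise EventLogError(f"unknown ethogram code {code!r}") from None


@dataclass(frozen=True)
class BehaviourEvent:
    """One coded behaviour: half-open interval ``[start_s, end_s)``."""

    calf_id: str
    code: str
    category: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise EventLogError(f"unknown category {self.category!r}")
        if self.start_s < 0:
            raise EventLogError(f"negative start time {self.start_s}")
        if self.end_s < self.start_s:
            raise EventLogError(
                f"event ends before it starts ({self.start_s}..{self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Bout:
    """A maximal episode of one behaviour category."""

    category: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise EventLogError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventLog:
    """A calf's ordered behavioural record over ``[obs_start_s, obs_end_s]``.

    Events of the same category must not overlap, with one ethogram-sanctioned
    exception: side-stepping (``f``) is a nested behaviour that may occur
    concurrently with standing.
    """

    calf_id: str
    obs_start_s: float
    obs_end_s: float
    events: list[BehaviourEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.obs_end_s < self.obs_start_s:
            raise EventLogError("observation window ends before it starts")
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.end_s))
        self._validate()

    def _validate(self) -> None:
        last_end: dict[str, float] = {}
        last_code: dict[str, str] = {}
        for ev in self.events:
            if ev.start_s < self.obs_start_s or ev.end_s > self.obs_end_s:
                raise EventLogError(
                    f"event [{ev.start_s}, {ev.end_s}) outside observation "
                    f"window [{self.obs_start_s}, {self.obs_end_s}]"
                )
            if ev.category in last_end and ev.start_s < last_end[ev.category]:
                # nested side-stepping within standing is permitted
                if "f" not in (ev.code, last_code[ev.category]):
                    raise EventLogError(
                        f"overlapping {ev.category} events at t={ev.start_s}"
                    )
            last_end[ev.category] = max(last_end.get(ev.category, -math.inf), ev.end_s)
            last_code[ev.category] = ev.code

    def events_in(self, categories: Iterable[str]) -> list[BehaviourEvent]:
        cats = set(categories)
        return [e for e in self.events if e.category in cats]


@dataclass(frozen=True)
class GroupBudget:
    duration_s: float
    bout_count: int


@dataclass(frozen=True)
class TimeBudget:
    """Durations and bout counts per behaviour group within one window."""

    window: tuple[float, float]
    groups: dict[str, GroupBudget]

    def __getitem__(self, group: str) -> GroupBudget:
        return self.groups[group]


# ---------------------------------------------------------------------------
# file I/O


def read_event_log(
    path,
    include_head_only_play: bool = False,
) -> EventLog:
    """Read a delimited-text event log.

    Expected columns: ``calf_id,code,category,start_s,end_s`` (``category``
    may be omitted; when present it is validated against the ethogram
    mapping).  Times are truncated to whole seconds.  Head-only play rows
    (``HS``) are dropped unless ``include_head_only_play`` is set.
    """
    try:
        frame = pd.read_csv(path, dtype={"calf_id": str, "code": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise EventLogError(f"cannot parse event log {path}: {exc}") from exc
    required = {"calf_id", "code", "start_s", "end_s"}
    missing = required - set(frame.columns)
    if missing:
        raise EventLogError(f"{path}: missing columns {sorted(missing)}")

    events: list[BehaviourEvent] = []
    calf_ids = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        code = row.code
        if code in HEAD_ONLY_PLAY_CODES and not include_head_only_play:
            continue
        try:
            category = category_for_code(code, include_head_only_play)
            start = math.floor(float(row.start_s))
            end = math.floor(float(row.end_s))
            if "category" in frame.columns and isinstance(row.category, str):
                if row.category != category:
                    raise EventLogError(
                        f"category {row.category!r} inconsistent with code {code!r}"
                    )
            events.append(
                BehaviourEvent(str(row.calf_id), code, category, start, end)
            )
            calf_ids.add(str(row.calf_id))
        except (EventLogError, TypeError, ValueError) as exc:
            raise EventLogError(f"{path}, line {i}: {exc}") from exc
    if len(calf_ids) > 1:
        raise EventLogError(f"{path}: multiple calf ids {sorted(calf_ids)}")

    calf_id = calf_ids.pop() if calf_ids else "unknown"
    obs_end = max((e.end_s for e in events), default=0.0)
    return EventLog(calf_id, 0.0, obs_end, events)


def write_event_log(log: EventLog, path) -> None:
    frame = pd.DataFrame(
        {
            "calf_id": [e.calf_id for e in log.events],
            "code": [e.code for e in log.events],
            "category": [e.category for e in log.events],
            "start_s": [e.start_s for e in log.events],
            "end_s": [e.end_s for e in log.events],
        }
    )
    frame.to_csv(path, index=False)


def boris_to_event_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Converter stub: map a BORIS-style tabular export to the event schema.

    Expects columns ``Subject``, ``Behavior``, ``Start (s)``, ``Stop (s)``;
    the behaviour column must already contain ethogram codes.
    """
    return pd.DataFrame(
        {
            "calf_id": frame["Subject"],
            "code": frame["Behavior"],
            "start_s": frame["Start (s)"],
            "end_s": frame["Stop (s)"],
        }
    )


# ---------------------------------------------------------------------------
# bouts and budgets


def _resolve_group(category: str) -> frozenset[str]:
    if category in BEHAVIOUR_GROUPS:
        return BEHAVIOUR_GROUPS[category]
    if category in CATEGORIES:
        return frozenset({category})
    raise EventLogError(f"unknown behaviour category or group {category!r}")


def _merge_intervals(
    intervals: Sequence[tuple[float, float]], max_gap_s: float
) -> list[tuple[float, float]]:
    """Merge sorted intervals whose gaps are <= max_gap_s; drop empty runs."""
    merged: list[list[float]] = []
    for start, end in sorted(intervals):
        if merged and start - merged[-1][1] <= max_gap_s:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e > s]


def extract_bouts(
    log: EventLog, category: str, max_gap_s: float = 1.0
) -> list[Bout]:
    """Merge events of a category (or group) into bouts.

    Runs of events separated by gaps of at most ``max_gap_s`` form one bout;
    a strictly longer gap terminates the bout.  Brief within-bout pauses are
    counted as part of the bout's duration.
    """
    if max_gap_s < 0:
        raise EventLogError("max_gap_s must be non-negative")
    cats = _resolve_group(category)
    label = category if category in BEHAVIOUR_GROUPS else category
    intervals = [(e.start_s, e.end_s) for e in log.events_in(cats)]
    bout_cat = "play" if cats == {"play"} else label
    return [
        Bout(bout_cat, s, e) for s, e in _merge_intervals(intervals, max_gap_s)
    ]


def time_budget(
    log: EventLog,
    window: tuple[float, float],
    max_gap_s: float = 1.0,
) -> TimeBudget:
    """Durations and bout counts per behaviour group within ``window``.

    Durations are the measure of the union of the group's events clipped to
    the window (union, not sum, so nested side-stepping is not
    double-counted).  A bout counts in a window if any part of it overlaps
    the window.  Meta (out-of-view/management) time is not subtracted here;
    interval-level exclusion happens at binarisation.
    """
    lo, hi = window
    if hi <= lo:
        raise EventLogError("empty time-budget window")
    if lo < log.obs_start_s or hi > log.obs_end_s:
        raise EventLogError(
            f"window [{lo}, {hi}] outside observation "
            f"[{log.obs_start_s}, {log.obs_end_s}]"
        )
    groups: dict[str, GroupBudget] = {}
    for name in BEHAVIOUR_GROUPS:
        bouts = extract_bouts(log, name, max_gap_s)
        # duration: union of events clipped to the window
        intervals = [
            (max(e.start_s, lo), min(e.end_s, hi))
            for e in log.events_in(BEHAVIOUR_GROUPS[name])
            if e.end_s > lo and e.start_s < hi
        ]
        duration = sum(e - s for s, e in _merge_intervals(intervals, 0.0))
        count = sum(1 for b in bouts if b.end_s > lo and b.start_s < hi)
        groups[name] = GroupBudget(duration_s=duration, bout_count=count)
    return TimeBudget(window=(lo, hi), groups=groups)
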