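"""Measure extraction from copying-task event logs.

A copying-task trial alternates *viewing sessions* (the observer
inspects items in the example arrangement) and *building sessions* (the
observer places items in the workspace).  From the raw event stream we
extract, per inspected item and building session, the two temporal
measures that drive the analyses:

* **cumulative viewing time** — the summed durations of all views of an
  item up to the building session (views after the item's correct
  placement are ignored);
* **delay** — the time from the end of the item's most recent view to
  its correct placement, or, for items left unplaced, to the end of the
  building session (right-censored).

At the end of each building session one row is emitted for every item
that had been inspected and was still unplaced when the session began,
so the same physical item can contribute rows to several sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "TrialLog",
    "Session",
    "MeasuredItem",
    "MalformedLogError",
    "segment_sessions",
    "extract_measured_items",
    "measured_items_frame",
    "bin_performance",
]

EVENT_KINDS = ("view_start", "view_end", "place", "session_start", "session_end")
SESSION_KINDS = ("viewing", "building")


class MalformedLogError(ValueError):
    """A trial log violates ordering, nesting, or alternation rules."""


@dataclass(frozen=True)
class Event:
    """One timestamped trial event.

    ``item_id`` holds the grid-cell identity for view/place events and
    the session kind ("viewing"/"building") for session markers.
    """

    kind: str
    item_id: str
    time_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("session_start", "session_end") and self.item_id not in SESSION_KINDS:
            raise ValueError(
                f"session marker must carry a session kind, got {self.item_id!r}"
            )


@dataclass
class TrialLog:
    """Time-ordered events of one copying-task trial."""

    participant_id: str
    trial_index: int
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise MalformedLogError(
                f"trial {self.trial_index} of {self.participant_id}: "
                "events not sorted by time"
            )

    def view_intervals(self):
        """(item_id, start_s, end_s) per completed view, time-ordered.

        Raises MalformedLogError on overlapping or unclosed views.
        """
        intervals = []
        open_item: Optional[tuple] = None
        for e in self.events:
            if e.kind == "view_start":
                if open_item is not None:
                    raise MalformedLogError(
                        f"view of item {e.item_id!r} starts at t={e.time_s} "
                        f"while item {open_item[0]!r} is still in view"
                    )
                open_item = (e.item_id, e.time_s)
            elif e.kind == "view_end":
                if open_item is None or open_item[0] != e.item_id:
                    raise MalformedLogError(
                        f"view_end of item {e.item_id!r} at t={e.time_s} "
                        "without matching view_start"
                    )
                intervals.append((e.item_id, open_item[1], e.time_s))
                open_item = None
        if open_item is not None:
            raise MalformedLogError(
                f"view of item {open_item[0]!r} opened at t={open_item[1]} never ends"
            )
        return intervals

    def placements(self):
        return [(e.item_id, e.time_s) for e in self.events if e.kind == "place"]


@dataclass(frozen=True)
class Session:
    kind: str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class MeasuredItem:
    """One analysis row: an inspected item at a building-session end."""

    participant_id: str
    trial_index: int
    building_session_index: int
    item_id: str
    viewing_time_s: float
    delay_s: float
    placed: bool
    n_views: int
    viewing_session_index_of_last_view: int


def _sessions_from_markers(log: TrialLog) -> list:
    sessions = []
    open_marker: Optional[Event] = None
    for e in log.events:
        if e.kind == "session_start":
            if open_marker is not None:
                raise MalformedLogError(
                    f"session_start ({e.item_id}) at t={e.time_s} while a "
                    f"{open_marker.item_id} session is open"
                )
            open_marker = e
        elif e.kind == "session_end":
            if open_marker is None or open_marker.item_id != e.item_id:
                raise MalformedLogError(
                    f"session_end ({e.item_id}) at t={e.time_s} without matching start"
                )
            sessions.append(Session(e.item_id, open_marker.time_s, e.time_s))
            open_marker = None
    if open_marker is not None:
        raise MalformedLogError(
            f"{open_marker.item_id} session opened at t={open_marker.time_s} never ends"
        )
    return sessions


def _sessions_from_events(log: TrialLog) -> list:
    """Infer session boundaries from views and placements alone.

    A viewing session spans a maximal run of consecutive views; the
    building session that follows spans from the run's last view end to
    the next run's first view start, or — for the final building
    session — to the last placement.  A trailing run of views with no
    subsequent building event yields no final building session.
    """
    intervals = log.view_intervals()
    if not intervals:
        return []
    places = log.placements()
    # split views into runs: a run breaks where a placement intervenes
    place_times = sorted(t for _, t in places)
    runs: list = [[intervals[0]]]
    for prev, cur in zip(intervals, intervals[1:]):
        gap_places = [t for t in place_times if prev[2] <= t <= cur[1]]
        if gap_places:
            runs.append([cur])
        else:
            runs[-1].append(cur)
    sessions = []
    for i, run in enumerate(runs):
        v_start, v_end = run[0][1], run[-1][2]
        sessions.append(Session("viewing", v_start, v_end))
        if i + 1 < len(runs):
            sessions.append(Session("building", v_end, runs[i + 1][0][1]))
        else:
            trailing = [t for t in place_times if t >= v_end]
            if trailing:
                sessions.append(Session("building", v_end, max(trailing)))
    return sessions


def segment_sessions(log: TrialLog) -> list:
    """Split a trial into alternating viewing/building sessions.

    Explicit session markers in the log are authoritative; without
    markers, boundaries are inferred from the view/placement stream.
    The returned sessions tile the trial's active span, alternate in
    kind, and are validated so that every view interval falls inside a
    viewing session and every placement inside a building session.
    """
    log.view_intervals()  # validates nesting early
    sessions = _sessions_from_markers(log)
    if not sessions:
        sessions = _sessions_from_events(log)
    for a, b in zip(sessions, sessions[1:]):
        if a.kind == b.kind:
            raise MalformedLogError(
                f"sessions do not alternate: {a.kind} at [{a.start_s}, {a.end_s}] "
                f"followed by {b.kind}"
            )
        if b.start_s < a.end_s:
            raise MalformedLogError("sessions overlap")
    viewing = [s for s in sessions if s.kind == "viewing"]
    building = [s for s in sessions if s.kind == "building"]
    for item, start, end in log.view_intervals():
        if not any(s.start_s <= start and end <= s.end_s for s in viewing):
            raise MalformedLogError(
                f"view of item {item!r} [{start}, {end}] outside any viewing session"
            )
    for item, t in log.placements():
        if not any(s.start_s <= t <= s.end_s for s in building):
            raise MalformedLogError(
                f"placement of item {item!r} at t={t} outside any building session"
            )
    return sessions


def extract_measured_items(log: TrialLog) -> list:
    """Emit one MeasuredItem per (inspected item, building session).

    At the end of each building session, every item viewed at least
    once before the session start and not yet placed at session start
    contributes a row.  Cumulative viewing time sums all views of the
    item up to its placement (or up to the session start if unplaced);
    the delay runs from the end of the most recent view to the
    placement, or to the session end under censoring.
    """
    sessions = segment_sessions(log)
    viewing_sessions = [s for s in sessions if s.kind == "viewing"]
    intervals = log.view_intervals()

    def viewing_session_index(start: float, end: float) -> int:
        for i, s in enumerate(viewing_sessions, start=1):
            if s.start_s <= start and end <= s.end_s:
                return i
        raise MalformedLogError(f"view [{start}, {end}] outside viewing sessions")

    views_by_item: dict = {}
    for item, start, end in intervals:
        views_by_item.setdefault(item, []).append(
            (start, end, viewing_session_index(start, end))
        )

    placed_at: dict = {}
    rows = []
    b_index = 0
    for s in sessions:
        if s.kind != "building":
            continue
        b_index += 1
        session_places = [
            (item, t) for item, t in log.placements() if s.start_s <= t <= s.end_s
        ]
        for item, t in session_places:
            if item not in views_by_item:
                warnings.warn(
                    f"placement of never-viewed item {item!r} at t={t}; row skipped",
                    stacklevel=2,
                )
        place_time = dict(session_places)
        candidates = [
            item
            for item in views_by_item
            if item not in placed_at
            and any(end <= s.start_s for _, end, _ in views_by_item[item])
        ]
        for item in candidates:
            if item in place_time:
                cutoff = place_time[item]
                placed = True
            else:
                cutoff = s.start_s
                placed = False
            counted = [v for v in views_by_item[item] if v[1] <= cutoff]
            if not counted:
                continue
            viewing_time = sum(end - start for start, end, _ in counted)
            last_view_end = max(end for _, end, _ in counted)
            last_view_session = max(idx for _, _, idx in counted)
            delay = (place_time[item] if placed else s.end_s) - last_view_end
            rows.append(
                MeasuredItem(
                    participant_id=log.participant_id,
                    trial_index=log.trial_index,
                    building_session_index=b_index,
                    item_id=item,
                    viewing_time_s=viewing_time,
                    delay_s=delay,
                    placed=placed,
                    n_views=len(counted),
                    viewing_session_index_of_last_view=last_view_session,
                )
            )
        for item, t in session_places:
            if item in views_by_item:
                placed_at[item] = t
    return rows


_FRAME_COLUMNS = [
    "participant_id",
    "trial_index",
    "building_session_index",
    "item_id",
    "viewing_time_s",
    "delay_s",
    "placed",
    "n_views",
    "viewing_session_index_of_last_view",
]


def measured_items_frame(logs: Iterable[TrialLog]) -> pd.DataFrame:
    """Extract measures from many logs into one analysis table."""
    rows = []
    for log in logs:
        rows.extend(extract_measured_items(log))
    if not rows:
        return pd.DataFrame(columns=_FRAME_COLUMNS)
    return pd.DataFrame([r.__dict__ for r in rows], columns=_FRAME_COLUMNS)


def bin_performance(
    rows: pd.DataFrame,
    viewing_edges: Optional[Sequence[float]] = None,
    delay_edges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Proportion of placed items per viewing-time and/or delay bin.

    Pass both edge lists for a two-way grid (e.g., 3 x 3 "short /
    medium / long" bins) or a single list for a marginal binning.
    Empty cells are reported with n = 0 and a missing proportion.
    Rows outside the edge span are excluded.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("rows must be nonempty")
    if viewing_edges is None and delay_edges is None:
        raise ValueError("provide viewing_edges, delay_edges, or both")
    df = rows.copy()
    keys = []
    for col, edges, name in (
        ("viewing_time_s", viewing_edges, "viewing_bin"),
        ("delay_s", delay_edges, "delay_bin"),
    ):
        if edges is None:
            continue
        edges = list(map(float, edges))
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"{name} edges must be strictly increasing")
        df[name] = pd.cut(df[col], bins=edges, include_lowest=True)
        keys.append(name)
    df = df.dropna(subset=keys)
    grouped = df.groupby(keys, observed=False)["placed"].agg(["size", "sum"])
    grouped.columns = ["n", "n_placed"]
    grouped["n_placed"] = grouped["n_placed"].astype(int)
    grouped["proportion"] = np.where(
        grouped["n"] > 0, grouped["n_placed"] / grouped["n"].replace(0, 1), np.nan
    )
    grouped.loc[grouped["n"] == 0, "proportion"] = np.nan
    return grouped.reset_index()
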