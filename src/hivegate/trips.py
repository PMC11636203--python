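"""Trip extraction from classified events, duration statistics, colony report.

A foraging trip is an exit event followed by the consecutive entry event of
the same tag.  Unknown events are discarded before pairing; among the
remaining classified events of each ID, each enter is paired with the latest
preceding unpaired exit (earlier exits are failed exits, enters with no
preceding exit are failed entries).  Trip duration is measured from the last
sighting while leaving to the first sighting on return
(``enter.t_start - exit.t_end``), the closest proxy for time spent outside
the hive; the start-to-start alternative would add the outbound tunnel
transit.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .logio import Detection
from .segmentation import ENTER, EXIT, UNKNOWN, Event

__all__ = [
    "Trip",
    "DurationStats",
    "ColonyReport",
    "extract_trips",
    "trip_statistics",
    "build_report",
    "write_events_spreadsheet",
    "events_to_frame",
]


@dataclass(frozen=True)
class Trip:
    tag_id: int
    exit_event: Event
    enter_event: Event

    def __post_init__(self) -> None:
        if self.exit_event.category != EXIT:
            raise ValueError("exit_event must be categorized 'exit'")
        if self.enter_event.category != ENTER:
            raise ValueError("enter_event must be categorized 'enter'")
        if not (self.exit_event.tag_id == self.enter_event.tag_id == self.tag_id):
            raise ValueError("trip events must share the trip's tag_id")
        if self.enter_event.t_start <= self.exit_event.t_end:
            raise ValueError("entry must start after the exit ends")

    @property
    def duration_seconds(self) -> float:
        return (self.enter_event.t_start - self.exit_event.t_end).total_seconds()


@dataclass(frozen=True)
class DurationStats:
    """Summary of trip durations; moments are None when n == 0."""

    n: int
    mean_seconds: float | None
    median_seconds: float | None
    mode_seconds: int | None  # most frequent whole-second duration, ties -> smallest
    bin_minutes: float
    histogram_counts: tuple[int, ...]  # counts per [k, k+1) * bin_minutes bin

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_seconds": self.mean_seconds,
            "median_seconds": self.median_seconds,
            "mode_seconds": self.mode_seconds,
            "bin_minutes": self.bin_minutes,
            "histogram_counts": list(self.histogram_counts),
        }


def extract_trips(events: Sequence[Event]) -> list[Trip]:
    """Pair classified events into trips (latest-exit-before-enter rule).

    Unknown events are removed first; an event with unset category is an
    error.  Per ID, each event joins at most one trip and trips are disjoint
    in time.
    """
    for ev in events:
        if ev.category is None:
            raise ValueError("event has unset category; run classify_event first")

    by_id: dict[int, list[Event]] = defaultdict(list)
    for ev in events:
        if ev.category != UNKNOWN:
            by_id[ev.tag_id].append(ev)

    trips: list[Trip] = []
    for tag_id in sorted(by_id):
        pending_exit: Event | None = None
        for ev in sorted(by_id[tag_id], key=lambda e: e.t_start):
            if ev.category == EXIT:
                pending_exit = ev  # a later exit supersedes a failed one
            elif pending_exit is not None:
                trips.append(Trip(tag_id, pending_exit, ev))
                pending_exit = None
            # enter with no pending exit: failed entry, dropped
    trips.sort(key=lambda t: (t.exit_event.t_start, t.tag_id))
    return trips


def trip_statistics(
    trips: Sequence[Trip] | Sequence[float],
    bin_minutes: float = 1.0,
) -> DurationStats:
    """Mean/median over raw seconds; mode at 1-s resolution; minute histogram.

    Accepts trips or raw durations in seconds.  An empty input yields
    ``n=0`` with all moments None rather than NaNs.
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    durations = [
        t.duration_seconds if isinstance(t, Trip) else float(t) for t in trips
    ]
    if any(d <= 0 for d in durations):
        raise ValueError("trip durations must be positive")
    if not durations:
        return DurationStats(0, None, None, None, bin_minutes, ())

    arr = np.asarray(durations)
    rounded = Counter(int(math.floor(d + 0.5)) for d in durations)
    best = max(rounded.values())
    mode = min(s for s, c in rounded.items() if c == best)

    n_bins = int(math.floor(max(durations) / 60.0 / bin_minutes)) + 1
    counts = [0] * n_bins
    for d in durations:
        counts[int(math.floor(d / 60.0 / bin_minutes))] += 1

    return DurationStats(
        n=len(durations),
        mean_seconds=float(arr.mean()),
        median_seconds=float(np.median(arr)),
        mode_seconds=mode,
        bin_minutes=bin_minutes,
        histogram_counts=tuple(counts),
    )


@dataclass(frozen=True)
class ColonyReport:
    """Counts, category fractions, per-ID tallies and duration statistics."""

    colony_label: str
    n_detections: int
    n_events: int
    mean_detections_per_event: float | None
    pct_enter: float | None
    pct_exit: float | None
    pct_unknown: float | None
    n_trips: int
    n_trips_below_cutoff: int
    cutoff_hours: float
    duration_stats: DurationStats
    per_id: pd.DataFrame = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "colony_label": self.colony_label,
            "n_detections": self.n_detections,
            "n_events": self.n_events,
            "mean_detections_per_event": self.mean_detections_per_event,
            "pct_enter": self.pct_enter,
            "pct_exit": self.pct_exit,
            "pct_unknown": self.pct_unknown,
            "n_trips": self.n_trips,
            "n_trips_below_cutoff": self.n_trips_below_cutoff,
            "cutoff_hours": self.cutoff_hours,
            "duration_stats": self.duration_stats.to_dict(),
            "per_id": self.per_id.to_dict(orient="list"),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        def pct(v):
            return "—" if v is None else f"{v:.2f}%"

        def secs(v):
            if v is None:
                return "—"
            m, s = divmod(float(v), 60.0)
            return f"{v:.2f} s ({int(m)} min {s:.0f} s)"

        ds = self.duration_stats
        lines = [
            f"Colony report: {self.colony_label}",
            f"  detections:            {self.n_detections}",
            f"  events:                {self.n_events}",
            f"  detections per event:  "
            + ("—" if self.mean_detections_per_event is None
               else f"{self.mean_detections_per_event:.2f}"),
            f"  enter / exit / unknown: {pct(self.pct_enter)} / "
            f"{pct(self.pct_exit)} / {pct(self.pct_unknown)}",
            f"  trips:                 {self.n_trips}",
            f"  trips < {self.cutoff_hours:g} h:           {self.n_trips_below_cutoff}",
            f"  trip duration mean:    {secs(ds.mean_seconds)}",
            f"  trip duration median:  {secs(ds.median_seconds)}",
            f"  trip duration mode:    {secs(ds.mode_seconds)}",
        ]
        return "\n".join(lines) + "\n"


def build_report(
    detections: Sequence[Detection],
    events: Sequence[Event],
    trips: Sequence[Trip],
    colony_label: str = "all",
    cutoff_hours: float = 2.0,
    bin_minutes: float = 1.0,
) -> ColonyReport:
    """Assemble the per-colony statistical report.

    Verifies input consistency: events must partition the detections and
    trips must reference the given events.
    """
    n_det = len(detections)
    n_ev = len(events)
    if sum(e.n_detections for e in events) != n_det:
        raise ValueError(
            "inconsistent inputs: events do not partition the detections "
            f"(sum of event sizes {sum(e.n_detections for e in events)} != "
            f"{n_det} detections)"
        )
    event_set = set(events)
    for t in trips:
        if t.exit_event not in event_set or t.enter_event not in event_set:
            raise ValueError(
                "inconsistent inputs: trip references an event not in the event list"
            )

    cats = Counter(e.category for e in events)
    if n_ev:
        pct_enter = 100.0 * cats.get(ENTER, 0) / n_ev
        pct_exit = 100.0 * cats.get(EXIT, 0) / n_ev
        pct_unknown = 100.0 * cats.get(UNKNOWN, 0) / n_ev
        mean_dpe = n_det / n_ev
    else:
        pct_enter = pct_exit = pct_unknown = mean_dpe = None

    cutoff_s = cutoff_hours * 3600.0
    below = sum(1 for t in trips if t.duration_seconds < cutoff_s)

    ids = sorted(
        {d.tag_id for d in detections}
        | {e.tag_id for e in events}
        | {t.tag_id for t in trips}
    )
    det_by = Counter(d.tag_id for d in detections)
    ev_by = Counter(e.tag_id for e in events)
    trip_by = Counter(t.tag_id for t in trips)
    per_id = pd.DataFrame(
        {
            "tag_id": ids,
            "detections": [det_by.get(i, 0) for i in ids],
            "events": [ev_by.get(i, 0) for i in ids],
            "trips": [trip_by.get(i, 0) for i in ids],
        }
    )

    return ColonyReport(
        colony_label=colony_label,
        n_detections=n_det,
        n_events=n_ev,
        mean_detections_per_event=mean_dpe,
        pct_enter=pct_enter,
        pct_exit=pct_exit,
        pct_unknown=pct_unknown,
        n_trips=len(trips),
        n_trips_below_cutoff=below,
        cutoff_hours=cutoff_hours,
        duration_stats=trip_statistics(list(trips), bin_minutes=bin_minutes),
        per_id=per_id,
    )


def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    """One row per event: id, span, size, category, net displacement."""
    return pd.DataFrame(
        {
            "tag_id": [e.tag_id for e in events],
            "t_start": [e.t_start for e in events],
            "t_end": [e.t_end for e in events],
            "n_detections": [e.n_detections for e in events],
            "category": [e.category for e in events],
            "net_displacement": [e.net_displacement for e in events],
        }
    )


def write_events_spreadsheet(
    events: Sequence[Event], out_dir: str | Path, stem: str = "Events_by_ID"
) -> tuple[Path, Path]:
    """Write all identified events as ``<stem>.csv`` and ``<stem>.xlsx``.

    Returns the two paths.  Zero events yield header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = events_to_frame(events)
    csv_path = out_dir / f"{stem}.csv"
    xlsx_path = out_dir / f"{stem}.xlsx"
    df.to_csv(csv_path, index=False)
    df.to_excel(xlsx_path, index=False, engine="openpyxl")
    return csv_path, xlsx_path
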