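"""Temporal-gap event segmentation and enter/exit/unknown classification.

Detections of one tag are grouped into an *event* whenever consecutive
sightings fall within ``gap_seconds`` of each other (default 60 s, boundary
inclusive); a longer silence starts a new event.  Because an exit and the
following entry can only be told apart when separated by more than the
grouping window, the minimum resolvable trip duration equals the window.

Events are then labeled by net displacement along the tunnel axis: positive
displacement (toward the hive-side image edge) at or beyond the threshold is
an ``enter``, the mirror case an ``exit``, anything else — including events
too short to define a direction — is ``unknown``.  Tag orientation is carried
through but not used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from typing import Sequence

from .logio import DEFAULT_FOV, Detection, FieldOfView

__all__ = ["Event", "SegmentationConfig", "group_events", "classify_event", "segment"]

ENTER = "enter"
EXIT = "exit"
UNKNOWN = "unknown"
CATEGORIES = (ENTER, EXIT, UNKNOWN)


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation stage.

    gap_seconds
        Maximum silence between consecutive same-ID detections inside one
        event.  A gap of exactly ``gap_seconds`` stays in the same event.
    displacement_threshold_frac
        Fraction of the tunnel-axis length the net displacement must reach
        for a direction call (default 0.25, i.e. 200 px at the 800-px axis).
    min_detections_for_direction
        Events with fewer detections are always ``unknown``.
    """

    gap_seconds: float = 60.0
    displacement_threshold_frac: float = 0.25
    min_detections_for_direction: int = 2

    def __post_init__(self) -> None:
        if self.gap_seconds <= 0:
            raise ValueError("gap_seconds must be positive")
        if not (0.0 < self.displacement_threshold_frac <= 1.0):
            raise ValueError("displacement_threshold_frac must be in (0, 1]")
        if self.min_detections_for_direction < 1:
            raise ValueError("min_detections_for_direction must be >= 1")

    def displacement_threshold_px(self, fov: FieldOfView) -> float:
        return self.displacement_threshold_frac * fov.tunnel_axis_length


@dataclass(frozen=True)
class Event:
    """Maximal run of same-ID detections with gaps within the grouping window."""

    tag_id: int
    detections: tuple[Detection, ...]
    category: str | None = None
    net_displacement: float | None = None

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("an event needs at least one detection")
        if any(d.tag_id != self.tag_id for d in self.detections):
            raise ValueError("all detections in an event must share tag_id")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    @property
    def t_start(self) -> datetime:
        return self.detections[0].timestamp

    @property
    def t_end(self) -> datetime:
        return self.detections[-1].timestamp

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def duration_seconds(self) -> float:
        return (self.t_end - self.t_start).total_seconds()


def _axis_position(det: Detection, fov: FieldOfView) -> float:
    return det.x if fov.tunnel_axis == "x" else det.y


def _toward_hive_sign(fov: FieldOfView) -> float:
    # hive at the low-coordinate edge => moving toward the hive decreases
    # the axis coordinate.
    return -1.0 if fov.hive_side in ("left", "top") else 1.0


def group_events(
    detections: Sequence[Detection],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Event]:
    """Group chronological detections into per-ID events (categories unset).

    Grouping is strictly per tag ID: interleaved detections of different IDs
    never interact.  Raises ``ValueError`` on non-chronological input (sort
    with :func:`hivegate.logio.parse_log` first).  Returned events are
    ordered by start time (ties keep per-ID formation order).
    """
    for a, b in zip(detections, detections[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError("detections must be chronological; parse_log sorts them")

    open_runs: dict[int, list[Detection]] = {}
    events: list[Event] = []

    def close(run: list[Detection]) -> None:
        events.append(Event(tag_id=run[0].tag_id, detections=tuple(run)))

    for det in detections:
        run = open_runs.get(det.tag_id)
        if run is None:
            open_runs[det.tag_id] = [det]
            continue
        gap = (det.timestamp - run[-1].timestamp).total_seconds()
        if gap <= cfg.gap_seconds:  # inclusive boundary
            run.append(det)
        else:
            close(run)
            open_runs[det.tag_id] = [det]
    for run in open_runs.values():
        close(run)

    events.sort(key=lambda e: e.t_start)
    return events


def classify_event(
    event: Event,
    fov: FieldOfView = DEFAULT_FOV,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> Event:
    """Return the event with ``category`` and ``net_displacement`` set.

    Net displacement is (last position - first position) projected on the
    tunnel axis, signed positive toward the hive side.
    """
    first = _axis_position(event.detections[0], fov)
    last = _axis_position(event.detections[-1], fov)
    disp = _toward_hive_sign(fov) * (last - first)

    if event.n_detections < cfg.min_detections_for_direction:
        category = UNKNOWN
    else:
        thr = cfg.displacement_threshold_px(fov)
        if disp >= thr:
            category = ENTER
        elif disp <= -thr:
            category = EXIT
        else:
            category = UNKNOWN
    return replace(event, category=category, net_displacement=disp)


def segment(
    detections: Sequence[Detection],
    fov: FieldOfView = DEFAULT_FOV,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Event]:
    """Convenience: group then classify in one pass."""
    return [classify_event(e, fov, cfg) for e in group_events(detections, cfg)]
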