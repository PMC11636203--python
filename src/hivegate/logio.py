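"""Detection-log dialect: parse, validate, write, and partition detection streams.

The hive-entrance camera emits one line per tag sighting.  The canonical
on-disk dialect is a headered CSV with fields

    timestamp,tag_id,x,y,theta,cpu_temp

where ``timestamp`` is naive local ISO-8601 with seconds (optional fractional
seconds), ``x``/``y`` are pixel coordinates inside the camera field of view,
``theta`` is the tag's forward-orientation angle in degrees ``[0, 360)`` and
``cpu_temp`` (degrees Celsius) may be empty.  Timestamps are deliberately
naive: the field hardware keeps local time and performs no timezone handling.

A pluggable ``line_parser`` hook lets other dialects be ingested without
touching the rest of the pipeline.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

HEADER = "timestamp,tag_id,x,y,theta,cpu_temp"

__all__ = [
    "Detection",
    "FieldOfView",
    "ColonyAllocation",
    "ParseError",
    "LogParseError",
    "DEFAULT_FOV",
    "DEFAULT_COLONY_SCHEME",
    "UNALLOCATED",
    "parse_log",
    "write_log",
    "colony_of",
    "detections_to_frame",
]


@dataclass(frozen=True, order=False)
class Detection:
    """One tag sighting: who, when, where, facing which way."""

    tag_id: int
    timestamp: datetime
    x: float
    y: float
    theta: float
    cpu_temp: float | None = None

    def validate(self, fov: "FieldOfView") -> None:
        if self.tag_id < 0:
            raise ValueError(f"tag_id must be non-negative, got {self.tag_id}")
        if not (0.0 <= self.x <= fov.width):
            raise ValueError(f"x={self.x} outside field of view [0, {fov.width}]")
        if not (0.0 <= self.y <= fov.height):
            raise ValueError(f"y={self.y} outside field of view [0, {fov.height}]")
        if not (0.0 <= self.theta < 360.0):
            raise ValueError(f"theta={self.theta} outside [0, 360)")


@dataclass(frozen=True)
class FieldOfView:
    """Camera-visible region of the entrance tunnel.

    ``hive_side`` names the image edge adjoining the hive interior; bees
    entering the hive move toward that edge.
    """

    width: int = 800
    height: int = 320
    hive_side: str = "left"

    _SIDES = ("left", "right", "top", "bottom")

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field-of-view dimensions must be positive")
        if self.hive_side not in self._SIDES:
            raise ValueError(f"hive_side must be one of {self._SIDES}")

    @property
    def tunnel_axis(self) -> str:
        """Axis of travel through the tunnel: 'x' for left/right hive side."""
        return "x" if self.hive_side in ("left", "right") else "y"

    @property
    def tunnel_axis_length(self) -> int:
        return self.width if self.tunnel_axis == "x" else self.height


DEFAULT_FOV = FieldOfView()


@dataclass(frozen=True)
class ColonyAllocation:
    """Inclusive tag-ID range assigned to one monitored colony."""

    colony_label: str
    id_low: int
    id_high: int

    def __contains__(self, tag_id: int) -> bool:
        return self.id_low <= tag_id <= self.id_high


#: Thousands-digit allocation: worker01..worker05 then the queen-hub colony.
DEFAULT_COLONY_SCHEME: tuple[ColonyAllocation, ...] = tuple(
    [ColonyAllocation(f"worker{i:02d}", i * 1000, i * 1000 + 999) for i in range(1, 6)]
    + [ColonyAllocation("queen", 6000, 6999)]
)

UNALLOCATED = "unallocated"


@dataclass(frozen=True)
class ParseError:
    """A malformed log line, reported rather than silently dropped."""

    line_number: int
    raw: str
    reason: str


class LogParseError(ValueError):
    """Raised in strict mode on the first malformed line."""

    def __init__(self, record: ParseError):
        self.record = record
        super().__init__(
            f"line {record.line_number}: {record.reason!s} ({record.raw!r})"
        )


def _format_timestamp(ts: datetime) -> str:
    if ts.microsecond:
        return ts.isoformat(sep="T", timespec="microseconds")
    return ts.isoformat(sep="T", timespec="seconds")


def _parse_canonical_line(line: str) -> Detection:
    parts = line.split(",")
    if len(parts) != 6:
        raise ValueError(f"expected 6 comma-separated fields, got {len(parts)}")
    ts_s, id_s, x_s, y_s, th_s, temp_s = (p.strip() for p in parts)
    ts = datetime.fromisoformat(ts_s)
    if ts.tzinfo is not None:
        raise ValueError("timestamps are naive local time; offset not allowed")
    temp = float(temp_s) if temp_s else None
    return Detection(
        tag_id=int(id_s),
        timestamp=ts,
        x=float(x_s),
        y=float(y_s),
        theta=float(th_s),
        cpu_temp=temp,
    )


def parse_log(
    lines: Iterable[str] | str | Path,
    fov: FieldOfView = DEFAULT_FOV,
    *,
    strict: bool = True,
    errors: list[ParseError] | None = None,
    line_parser: Callable[[str], Detection] = _parse_canonical_line,
) -> list[Detection]:
    """Parse a detection log into a chronologically ordered detection list.

    Parameters
    ----------
    lines
        An iterable of lines, a whole-log string, or a path to a log file.
    fov
        Field of view used to validate positions.
    strict
        If True (default), the first malformed line raises
        :class:`LogParseError`.  If False, malformed lines are logged,
        appended to *errors* when given, and skipped.
    errors
        Optional sink for :class:`ParseError` records in lenient mode.
    line_parser
        Hook for ingesting non-canonical dialects; must map one line to a
        :class:`Detection`.

    Detections are returned sorted by timestamp; ties keep input order
    (stable sort).
    """
    if isinstance(lines, Path):
        lines = lines.read_text(encoding="utf-8").splitlines()
    elif isinstance(lines, str):
        lines = lines.splitlines()

    out: list[Detection] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.strip() == HEADER:
            continue
        try:
            det = line_parser(line)
            det.validate(fov)
        except (ValueError, OverflowError) as exc:
            rec = ParseError(lineno, line, str(exc))
            if strict:
                raise LogParseError(rec) from exc
            logger.warning("skipping malformed log line %d: %s", lineno, exc)
            if errors is not None:
                errors.append(rec)
            continue
        out.append(det)
    out.sort(key=lambda d: d.timestamp)  # stable: ties keep input order
    return out


def write_log(
    detections: Sequence[Detection],
    path: str | Path | None = None,
    fov: FieldOfView = DEFAULT_FOV,
) -> str:
    """Serialize detections to the canonical dialect (header + one line each).

    Output is chronological regardless of input order.  Returns the text; if
    *path* is given the text is also written there (UTF-8, LF endings).
    """
    for det in detections:
        det.validate(fov)
    ordered = sorted(detections, key=lambda d: d.timestamp)
    buf = io.StringIO()
    buf.write(HEADER + "\n")
    for d in ordered:
        # repr gives the shortest decimal that parses back to the same float,
        # so write->parse is lossless and values never round out of range
        temp = "" if d.cpu_temp is None else repr(float(d.cpu_temp))
        buf.write(
            f"{_format_timestamp(d.timestamp)},{d.tag_id},"
            f"{float(d.x)!r},{float(d.y)!r},{float(d.theta)!r},{temp}\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text


def colony_of(
    tag_id: int,
    scheme: Sequence[ColonyAllocation] = DEFAULT_COLONY_SCHEME,
) -> str:
    """Colony label owning *tag_id*, or ``"unallocated"`` if no range matches.

    Ranges must be disjoint; the first (unique) containing range wins.
    """
    for alloc in scheme:
        if tag_id in alloc:
            return alloc.colony_label
    return UNALLOCATED


def detections_to_frame(detections: Sequence[Detection]):
    """Detections as a pandas DataFrame (one row per sighting)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "timestamp": [d.timestamp for d in detections],
            "tag_id": [d.tag_id for d in detections],
            "x": [d.x for d in detections],
            "y": [d.y for d in detections],
            "theta": [d.theta for d in detections],
            "cpu_temp": [d.cpu_temp for d in detections],
        }
    )
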