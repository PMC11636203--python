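"""Synthetic entrance traffic with ground truth.

Emulates multi-day detection streams from tagged bees crossing an entrance
tunnel under a camera: foraging trips, cleansing flights (seconds to a
minute), orientation flights (250-300 s), failed exits/entries, and loitering
near the entrance.  Two failure modes of the real system are modeled: a tag
is only read in a fraction of frames while in view (fast-moving bees), and an
entire traversal can yield no detections (bees crawling upside down).

Randomness design: every random draw (schedules, durations, per-frame
detection uniforms) is made from one seeded generator *independently of the
detection probabilities*, which enter only as comparison thresholds.  Runs
that differ only in ``p_frame_detect`` therefore share identical traffic and
coupled detection draws (common random numbers), which makes recovery-rate
degradation across probability ladders monotone by construction rather than
merely in expectation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .logio import DEFAULT_FOV, Detection, FieldOfView
from .trips import Trip

__all__ = [
    "TrafficScenario",
    "Excursion",
    "GroundTruth",
    "RecoveryResult",
    "simulate_traffic",
    "recovery_rate",
    "perfect_scenario",
]

BEHAVIORS = (
    "foraging_trip",
    "cleansing_flight",
    "orientation_flight",
    "failed_exit",
    "failed_entry",
    "loiter",
)
EXCURSION_BEHAVIORS = ("foraging_trip", "cleansing_flight", "orientation_flight")

DEFAULT_MIX = {
    "foraging_trip": 0.50,
    "cleansing_flight": 0.15,
    "orientation_flight": 0.05,
    "failed_exit": 0.10,
    "failed_entry": 0.10,
    "loiter": 0.10,
}

# Log-normal foraging-trip durations: mode 120 s, raw mean ~18.6 min —
# strongly right-skewed, most trips in the 1-4 min range.
DEFAULT_TRIP_MODEL = ("lognormal", {"mu": 6.2752, "sigma": 1.2198})


@dataclass(frozen=True)
class TrafficScenario:
    """Study conditions for one synthetic traffic run."""

    n_bees: int = 50
    id_range: tuple[int, int] = (5000, 5099)
    duration_days: float = 4.0
    behavior_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX)
    )
    trip_duration_model: tuple[str, dict] = DEFAULT_TRIP_MODEL
    min_trip_duration_s: float = 90.0
    orientation_duration_range: tuple[float, float] = (250.0, 300.0)
    cleansing_duration_range: tuple[float, float] = (5.0, 60.0)
    traversal_speed_px_s: float = 400.0
    frame_rate: float = 15.0
    p_frame_detect: float = 0.15
    p_traversal_missed: float = 0.10
    activities_per_bee_day: float = 6.0
    activity_window_hours: tuple[float, float] = (7.0, 19.0)
    start: datetime = datetime(2024, 6, 1)
    fov: FieldOfView = DEFAULT_FOV
    max_excursions: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees < 0:
            raise ValueError("n_bees must be non-negative")
        lo, hi = self.id_range
        if self.n_bees > hi - lo + 1:
            raise ValueError("id_range too small for n_bees")
        total = sum(self.behavior_mix.values())
        if self.behavior_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"behavior_mix must sum to 1, got {total}")
        for name, p in self.behavior_mix.items():
            if name not in BEHAVIORS:
                raise ValueError(f"unknown behavior {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError("behavior probabilities must be in [0, 1]")
        for p in (self.p_frame_detect, self.p_traversal_missed):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.frame_rate <= 0 or self.traversal_speed_px_s <= 0:
            raise ValueError("frame_rate and traversal speed must be positive")


@dataclass(frozen=True)
class Excursion:
    """One true absence from the hive: out through the tunnel and back.

    ``t_leave`` is the moment the bee leaves the field of view outward;
    ``t_return`` the moment it reappears at the outer edge.  A traversal is
    *detectable* unless the whole pass was missed (tag obscured throughout).
    """

    tag_id: int
    t_leave: datetime
    t_return: datetime
    behavior: str
    out_detectable: bool
    ret_detectable: bool

    @property
    def duration_seconds(self) -> float:
        return (self.t_return - self.t_leave).total_seconds()

    @property
    def detectable(self) -> bool:
        return self.out_detectable and self.ret_detectable


@dataclass(frozen=True)
class GroundTruth:
    excursions: tuple[Excursion, ...]
    n_traversals: int
    n_missed_traversals: int

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "n_traversals": self.n_traversals,
            "n_missed_traversals": self.n_missed_traversals,
            "excursions": [
                {
                    "tag_id": e.tag_id,
                    "t_leave": e.t_leave.isoformat(),
                    "t_return": e.t_return.isoformat(),
                    "behavior": e.behavior,
                    "out_detectable": e.out_detectable,
                    "ret_detectable": e.ret_detectable,
                }
                for e in self.excursions
            ],
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


class _Clock:
    """Datetime arithmetic on a float seconds offset (microsecond rounding)."""

    def __init__(self, epoch: datetime):
        self.epoch = epoch

    def at(self, seconds: float) -> datetime:
        return self.epoch + timedelta(seconds=seconds)


def _sample_trip_duration(rng: np.random.Generator, sc: TrafficScenario) -> float:
    family, params = sc.trip_duration_model
    for _ in range(1000):
        if family == "lognormal":
            d = float(rng.lognormal(params["mu"], params["sigma"]))
        elif family == "uniform":
            d = float(rng.uniform(params["low"], params["high"]))
        elif family == "exponential":
            d = float(rng.exponential(params["scale"]))
        else:
            raise ValueError(f"unknown trip_duration_model family {family!r}")
        if d >= sc.min_trip_duration_s:
            return d
    raise RuntimeError("trip duration model rarely exceeds the minimum duration")


def _heading(direction: float, fov: FieldOfView) -> float:
    # direction +1 = away from hive along the tunnel axis
    if fov.hive_side == "left":
        return 0.0 if direction > 0 else 180.0
    if fov.hive_side == "right":
        return 180.0 if direction > 0 else 0.0
    if fov.hive_side == "top":
        return 90.0 if direction > 0 else 270.0
    return 270.0 if direction > 0 else 90.0


def _frames_along(
    rng: np.random.Generator,
    sc: TrafficScenario,
    clock: _Clock,
    tag_id: int,
    t0: float,
    axis_positions: np.ndarray,
    heading_deg: np.ndarray,
    missed: bool,
    detections: list[Detection],
) -> None:
    """Emit per-frame detections for a path sampled at the frame rate."""
    fov = sc.fov
    n = len(axis_positions)
    # detection uniforms are always drawn so runs differing only in
    # p_frame_detect share the same stream (common random numbers)
    u = rng.uniform(size=n)
    cross0 = rng.uniform(0.15, 0.85) * (
        fov.height if fov.tunnel_axis == "x" else fov.width
    )
    cross_jitter = np.clip(
        cross0 + np.cumsum(rng.normal(0.0, 3.0, size=n)),
        2.0,
        (fov.height if fov.tunnel_axis == "x" else fov.width) - 2.0,
    )
    theta = np.mod(heading_deg + rng.normal(0.0, 8.0, size=n), 360.0)
    if missed:
        return
    for k in range(n):
        if u[k] >= sc.p_frame_detect:
            continue
        if fov.tunnel_axis == "x":
            x, y = float(axis_positions[k]), float(cross_jitter[k])
        else:
            x, y = float(cross_jitter[k]), float(axis_positions[k])
        detections.append(
            Detection(
                tag_id=tag_id,
                timestamp=clock.at(t0 + k / sc.frame_rate),
                x=x,
                y=y,
                theta=float(theta[k]),
                cpu_temp=None,
            )
        )


def _traversal_positions(sc: TrafficScenario, outbound: bool) -> np.ndarray:
    """Axis positions of a full tunnel crossing sampled at the frame rate."""
    axis_len = sc.fov.tunnel_axis_length
    cross_time = axis_len / sc.traversal_speed_px_s
    n = int(math.floor(cross_time * sc.frame_rate)) + 1
    if n < 2:
        warnings.warn(
            "traversal faster than the frame interval: no usable frame lands "
            "in the field of view",
            stacklevel=2,
        )
        return np.empty(0)
    pos = np.minimum(
        np.arange(n) / sc.frame_rate * sc.traversal_speed_px_s, axis_len
    )
    hive_low = sc.fov.hive_side in ("left", "top")
    away = pos if hive_low else axis_len - pos
    return away if outbound else away[::-1]


def simulate_traffic(
    scenario: TrafficScenario,
) -> tuple[list[Detection], GroundTruth]:
    """Generate a detection stream plus ground truth for *scenario*.

    Identical scenarios (including the seed) produce identical output.  The
    returned detections are chronological and valid input for
    :func:`hivegate.logio.write_log`.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    clock = _Clock(sc.start)
    fov = sc.fov
    axis_len = fov.tunnel_axis_length
    cross_time = axis_len / sc.traversal_speed_px_s

    behaviors = sorted(sc.behavior_mix)
    probs = np.array([sc.behavior_mix[b] for b in behaviors])

    detections: list[Detection] = []
    excursions: list[Excursion] = []
    counters = {"traversals": 0, "missed": 0}
    cap_hit = False

    w_lo, w_hi = sc.activity_window_hours
    window_len = (w_hi - w_lo) * 3600.0
    mean_gap = window_len / max(sc.activities_per_bee_day, 1e-9)

    for bee in range(sc.n_bees):
        if cap_hit:
            break
        tag_id = sc.id_range[0] + bee
        for day in range(int(math.ceil(sc.duration_days))):
            if cap_hit:
                break
            day_frac = min(1.0, sc.duration_days - day)
            w_start = day * 86400.0 + w_lo * 3600.0
            w_end = w_start + window_len * day_frac
            t = w_start + float(rng.uniform(0.0, mean_gap))
            while t < w_end:
                behavior = behaviors[int(rng.choice(len(behaviors), p=probs))]
                t_end_activity = _emit_activity(
                    rng, sc, clock, tag_id, t, behavior,
                    detections, excursions, counters,
                )
                if behavior in EXCURSION_BEHAVIORS:
                    if (
                        sc.max_excursions is not None
                        and len(excursions) >= sc.max_excursions
                    ):
                        cap_hit = True
                        break
                t = t_end_activity + 90.0 + float(rng.exponential(mean_gap))

    n_traversals, n_missed = counters["traversals"], counters["missed"]
    detections.sort(key=lambda d: d.timestamp)
    return detections, GroundTruth(
        excursions=tuple(excursions),
        n_traversals=n_traversals,
        n_missed_traversals=n_missed,
    )


def _emit_activity(
    rng: np.random.Generator,
    sc: TrafficScenario,
    clock: _Clock,
    tag_id: int,
    t: float,
    behavior: str,
    detections: list[Detection],
    excursions: list[Excursion],
    counters: dict[str, int],
) -> float:
    """Emit one activity starting at offset *t*; returns its end offset."""
    fov = sc.fov
    axis_len = fov.tunnel_axis_length
    cross_time = axis_len / sc.traversal_speed_px_s
    hive_low = fov.hive_side in ("left", "top")

    def missed_draw() -> bool:
        counters["traversals"] += 1
        missed = bool(rng.uniform() < sc.p_traversal_missed)
        if missed:
            counters["missed"] += 1
        return missed

    if behavior in EXCURSION_BEHAVIORS:
        if behavior == "foraging_trip":
            d = _sample_trip_duration(rng, sc)
        elif behavior == "orientation_flight":
            d = float(rng.uniform(*sc.orientation_duration_range))
        else:
            d = float(rng.uniform(*sc.cleansing_duration_range))
        out_pos = _traversal_positions(sc, outbound=True)
        ret_pos = _traversal_positions(sc, outbound=False)
        out_missed = missed_draw()
        ret_missed = missed_draw()
        t_leave = t + cross_time
        t_return = t_leave + d
        _frames_along(
            rng, sc, clock, tag_id, t,
            out_pos, np.full(len(out_pos), _heading(+1.0, fov)),
            out_missed, detections,
        )
        _frames_along(
            rng, sc, clock, tag_id, t_return,
            ret_pos, np.full(len(ret_pos), _heading(-1.0, fov)),
            ret_missed, detections,
        )
        excursions.append(
            Excursion(
                tag_id=tag_id,
                t_leave=clock.at(t_leave),
                t_return=clock.at(t_return),
                behavior=behavior,
                out_detectable=not out_missed and len(out_pos) > 0,
                ret_detectable=not ret_missed and len(ret_pos) > 0,
            )
        )
        return t_return + cross_time

    if behavior in ("failed_exit", "failed_entry"):
        frac = float(rng.uniform(0.3, 0.6))
        turn = frac * axis_len
        n_half = max(2, int(math.floor(turn / sc.traversal_speed_px_s * sc.frame_rate)))
        leg = np.arange(n_half) / sc.frame_rate * sc.traversal_speed_px_s
        path = np.concatenate([leg, turn - leg])
        path = np.clip(path, 0.0, axis_len)
        if behavior == "failed_exit":
            pos = path if hive_low else axis_len - path
            head = np.where(np.diff(path, prepend=-1.0) >= 0,
                            _heading(+1.0, fov), _heading(-1.0, fov))
        else:
            pos = (axis_len - path) if hive_low else path
            head = np.where(np.diff(path, prepend=-1.0) >= 0,
                            _heading(-1.0, fov), _heading(+1.0, fov))
        missed = missed_draw()
        _frames_along(rng, sc, clock, tag_id, t, pos, head, missed, detections)
        return t + len(path) / sc.frame_rate

    # loiter: low-net-displacement cluster near the tunnel middle
    dwell = float(rng.uniform(10.0, 60.0))
    n = max(2, int(dwell * sc.frame_rate))
    center = float(rng.uniform(0.3, 0.7)) * axis_len
    pos = np.clip(center + np.cumsum(rng.normal(0.0, 4.0, size=n)), 0.0, axis_len)
    head = np.mod(rng.normal(0.0, 90.0, size=n), 360.0)
    missed = missed_draw()
    _frames_along(rng, sc, clock, tag_id, t, pos, head, missed, detections)
    return t + dwell



@dataclass(frozen=True)
class RecoveryResult:
    rate: float
    n_recovered: int
    n_detectable: int
    duration_errors_s: tuple[float, ...]


def recovery_rate(
    truth: GroundTruth,
    trips: Sequence[Trip],
    tolerance_s: float,
) -> RecoveryResult:
    """Fraction of detectable true excursions recovered as trips.

    An excursion counts as recovered when a same-ID trip overlaps it in time
    and the trip duration agrees with the true absence within *tolerance_s*.
    Each trip is matched to at most one excursion (greedy, chronological).
    """
    by_id: dict[int, list[Trip]] = {}
    for tr in sorted(trips, key=lambda t: t.exit_event.t_end):
        by_id.setdefault(tr.tag_id, []).append(tr)
    used: set[int] = set()
    recovered = 0
    errors: list[float] = []
    detectable = [e for e in truth.excursions if e.detectable]
    for exc in sorted(detectable, key=lambda e: e.t_leave):
        for tr in by_id.get(exc.tag_id, ()):
            if id(tr) in used:
                continue
            if tr.exit_event.t_end > exc.t_return or tr.enter_event.t_start < exc.t_leave:
                continue  # no temporal overlap
            err = abs(tr.duration_seconds - exc.duration_seconds)
            if err <= tolerance_s:
                used.add(id(tr))
                recovered += 1
                errors.append(err)
                break
    n_det = len(detectable)
    rate = recovered / n_det if n_det else 0.0
    return RecoveryResult(rate, recovered, n_det, tuple(errors))


def perfect_scenario(
    n_excursions: int = 500, seed: int = 7, **overrides
) -> TrafficScenario:
    """Clean-traversal conditions: every frame detected, nothing missed.

    Foraging-only traffic capped at *n_excursions*; used to verify that the
    pipeline recovers simulated trips exactly when detection is perfect.
    """
    params = dict(
        n_bees=50,
        duration_days=30.0,
        behavior_mix={"foraging_trip": 1.0},
        p_frame_detect=1.0,
        p_traversal_missed=0.0,
        max_excursions=n_excursions,
        seed=seed,
    )
    params.update(overrides)
    return TrafficScenario(**params)
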