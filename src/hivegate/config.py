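"""Run configuration: aggregate of field-of-view, segmentation and reporting
settings, loadable from a YAML file with flag overrides winning."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .logio import DEFAULT_COLONY_SCHEME, ColonyAllocation, FieldOfView
from .segmentation import SegmentationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; defaults are the field deployment's
    parameters (60-s grouping window, 800x320 field of view, 2-h cutoff)."""

    fov: FieldOfView = FieldOfView()
    segmentation: SegmentationConfig = SegmentationConfig()
    colony_scheme: tuple[ColonyAllocation, ...] = DEFAULT_COLONY_SCHEME
    cutoff_hours: float = 2.0
    bin_minutes: float = 1.0
    out_dir: Path = Path("hivegate_out")
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_hours <= 0:
            raise ValueError("cutoff_hours must be positive")


def _scheme_from_mapping(mapping: dict[str, Sequence[int]]):
    allocs = []
    for label, (lo, hi) in mapping.items():
        allocs.append(ColonyAllocation(label, int(lo), int(hi)))
    allocs.sort(key=lambda a: a.id_low)
    for a, b in zip(allocs, allocs[1:]):
        if b.id_low <= a.id_high:
            raise ValueError(f"colony ranges overlap: {a} and {b}")
    return tuple(allocs)


def load_config(
    path: str | Path | None = None, **overrides: Any
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Recognized keys: ``fov_width``, ``fov_height``, ``hive_side``,
    ``gap_seconds``, ``displacement_threshold_frac``,
    ``min_detections_for_direction``, ``colonies`` (label -> [low, high]),
    ``cutoff_hours``, ``bin_minutes``, ``out_dir``, ``verbose``.
    Overrides win over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded:
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    fov = FieldOfView(
        width=int(data.get("fov_width", 800)),
        height=int(data.get("fov_height", 320)),
        hive_side=data.get("hive_side", "left"),
    )
    seg = SegmentationConfig(
        gap_seconds=float(data.get("gap_seconds", 60.0)),
        displacement_threshold_frac=float(
            data.get("displacement_threshold_frac", 0.25)
        ),
        min_detections_for_direction=int(
            data.get("min_detections_for_direction", 2)
        ),
    )
    scheme = (
        _scheme_from_mapping(data["colonies"])
        if "colonies" in data
        else DEFAULT_COLONY_SCHEME
    )
    return RunConfig(
        fov=fov,
        segmentation=seg,
        colony_scheme=scheme,
        cutoff_hours=float(data.get("cutoff_hours", 2.0)),
        bin_minutes=float(data.get("bin_minutes", 1.0)),
        out_dir=Path(data.get("out_dir", "hivegate_out")),
        verbose=bool(data.get("verbose", False)),
    )
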