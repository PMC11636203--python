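"""Report histograms and per-event trajectory figures.

Two colony-report plots (grouped detections/events/trips bars per tag ID, and
trips per duration range in minutes) plus per-event trajectory panels that
draw each detection as a position + orientation vector on the camera's field
of view, annotated with category and timestamps.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .logio import DEFAULT_FOV, FieldOfView
from .segmentation import Event
from .trips import ColonyReport

__all__ = ["plot_id_histogram", "plot_duration_histogram", "plot_event"]


def plot_id_histogram(report: ColonyReport, path: str | Path) -> Path:
    """Grouped bars of detections, events and trips per tag ID."""
    df = report.per_id
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(df)), 4))
    idx = np.arange(len(df))
    w = 0.27
    ax.bar(idx - w, df["detections"], w, label="detections")
    ax.bar(idx, df["events"], w, label="events")
    ax.bar(idx + w, df["trips"], w, label="trips")
    ax.set_xticks(idx)
    ax.set_xticklabels(df["tag_id"], rotation=90, fontsize=7)
    ax.set_xlabel("tag ID")
    ax.set_ylabel("count")
    ax.set_title(f"Detections / events / trips per ID — {report.colony_label}")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_duration_histogram(report: ColonyReport, path: str | Path) -> Path:
    """Number of trips per duration range (minutes)."""
    ds = report.duration_stats
    fig, ax = plt.subplots(figsize=(8, 4))
    if ds.n:
        edges = np.arange(len(ds.histogram_counts) + 1) * ds.bin_minutes
        ax.bar(edges[:-1], ds.histogram_counts, width=ds.bin_minutes,
               align="edge", edgecolor="black", linewidth=0.3)
        ax.set_xlim(0, edges[-1])
    ax.set_xlabel(f"trip duration (bins of {ds.bin_minutes:g} min)")
    ax.set_ylabel("trips")
    subtitle = (
        f"n={ds.n}"
        + ("" if ds.mean_seconds is None else
           f", mean {ds.mean_seconds / 60:.1f} min, median "
           f"{ds.median_seconds / 60:.1f} min, mode {ds.mode_seconds} s")
    )
    ax.set_title(f"Trip durations — {report.colony_label} ({subtitle})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_event(
    event: Event,
    path: str | Path,
    fov: FieldOfView = DEFAULT_FOV,
    arrow_px: float = 25.0,
) -> Path:
    """One event as detection vectors on the field-of-view canvas.

    Each detection is an arrow at its (x, y) position pointing along the
    tag's forward orientation; the panel is annotated with the event's
    category and start/end timestamps.
    """
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 8 * fov.height / fov.width))
    )
    xs = [d.x for d in event.detections]
    ys = [d.y for d in event.detections]
    us = [arrow_px * math.cos(math.radians(d.theta)) for d in event.detections]
    vs = [arrow_px * math.sin(math.radians(d.theta)) for d in event.detections]
    ax.quiver(xs, ys, us, vs, angles="xy", scale_units="xy", scale=1,
              color="tab:blue", width=0.004)
    ax.plot(xs, ys, ":", color="gray", linewidth=0.8)
    ax.plot(xs[0], ys[0], "go", label="first")
    ax.plot(xs[-1], ys[-1], "rs", label="last")
    ax.set_xlim(0, fov.width)
    ax.set_ylim(fov.height, 0)  # image coordinates, origin top-left
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    cat = event.category or "unclassified"
    ax.set_title(
        f"ID {event.tag_id} — {cat} — {event.t_start.isoformat()} → "
        f"{event.t_end.isoformat()} ({event.n_detections} detections)"
    )
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
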