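"""Detector-adapter contract plus a reference detector for rendered frames.

The processing pipeline never depends on a particular tag-detection library:
anything honoring the narrow :class:`TagDetector` protocol (raster in, list
of id/x/y/theta sightings out) can be injected, and every log-based stage
works with no detector at all.  :class:`GridTemplateDetector` is the shipped
reference implementation: it finds the family's fixed black/white border ring
by FFT cross-correlation on axis-aligned, unrotated frames — sufficient for
synthetic frames and tests, not a replacement for a full detector on field
imagery (no rotation/perspective handling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import signal

from .layout import TagLayout
from .render import AmbiguousCellError, decode_raster, dilate_white

__all__ = ["TagSighting", "TagDetector", "GridTemplateDetector", "detect_tags"]


@dataclass(frozen=True)
class TagSighting:
    """One tag found in one frame (frame coordinates, no timestamp)."""

    tag_id: int
    x: float
    y: float
    theta: float


@runtime_checkable
class TagDetector(Protocol):
    def detect(self, frame: np.ndarray) -> list[TagSighting]: ...


class GridTemplateDetector:
    """Correlate the border-ring template against a binarized frame.

    Parameters
    ----------
    layout
        Cell-role grid of the family.
    cell_pixels
        Apparent cell size in the frame (tags must be rendered at this
        scale, axis-aligned).
    codebook
        Optional list of family codewords; a decoded codeword maps to its
        index (the tag ID).  Without a codebook the raw codeword is the ID.
    min_score
        Fraction of the perfect border-correlation score required to accept
        a candidate (default 0.99: all border cells must essentially match).
    """

    def __init__(
        self,
        layout: TagLayout,
        cell_pixels: int = 8,
        codebook: Sequence[int] | None = None,
        min_score: float = 0.99,
    ):
        self.layout = layout
        self.cell_pixels = cell_pixels
        self.codebook = {c: i for i, c in enumerate(codebook)} if codebook else None
        self.min_score = min_score
        roles = layout.role_array()
        cell_t = np.zeros(roles.shape, dtype=np.float64)
        cell_t[roles == "w"] = 1.0
        cell_t[roles == "b"] = -1.0
        self._template = np.kron(cell_t, np.ones((cell_pixels, cell_pixels)))
        self._perfect = float(np.abs(self._template).sum())

    def detect(self, frame: np.ndarray) -> list[TagSighting]:
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim != 2:
            raise ValueError("expected a single-channel frame")
        side = self.layout.size * self.cell_pixels
        if frame.shape[0] < side or frame.shape[1] < side:
            return []
        binar = np.where(frame > 127.5, 1.0, -1.0)
        score = signal.fftconvolve(binar, self._template[::-1, ::-1], mode="valid")

        cutoff = self.min_score * self._perfect
        rows, cols = np.nonzero(score >= cutoff)
        if rows.size == 0:
            return []
        order = np.argsort(score[rows, cols])[::-1]
        accepted: list[tuple[int, int]] = []
        for k in order:
            r, c = int(rows[k]), int(cols[k])
            if all(abs(r - ar) >= side // 2 or abs(c - ac) >= side // 2
                   for ar, ac in accepted):
                accepted.append((r, c))

        sightings = []
        for r, c in accepted:
            try:
                codeword = decode_raster(
                    frame, self.layout, origin=(r, c), cell_pixels=self.cell_pixels
                )
            except AmbiguousCellError:
                continue
            if self.codebook is not None:
                if codeword not in self.codebook:
                    continue
                tag_id = self.codebook[codeword]
            else:
                tag_id = codeword
            sightings.append(
                TagSighting(
                    tag_id=tag_id,
                    x=c + side / 2.0,
                    y=r + side / 2.0,
                    theta=0.0,
                )
            )
        sightings.sort(key=lambda s: (s.y, s.x))
        return sightings


def detect_tags(
    frame: np.ndarray,
    detector: TagDetector,
    dilate: bool = False,
    kernel_px: int = 3,
) -> list[TagSighting]:
    """Run an injected detector on a frame, optionally dilating white first.

    The dilation pre-pass counters ink bleeding on printed tags and can be
    switched off for clean imagery.  Returned positions are checked against
    the frame bounds.
    """
    if detector is None:
        raise ValueError(
            "no detector injected; log-based pipelines do not require one"
        )
    frame = np.asarray(frame)
    if dilate:
        frame = dilate_white(frame, kernel_px=kernel_px)
    found = detector.detect(frame)
    h, w = frame.shape[:2]
    for s in found:
        if not (0 <= s.x <= w and 0 <= s.y <= h):
            raise ValueError(f"detector returned out-of-frame position {s}")
    return found
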