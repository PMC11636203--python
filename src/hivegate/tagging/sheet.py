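"""Printable tag sheets: grid layout in millimetres, SVG / PNG / PDF export.

Each placed tag carries the printed square, a magenta cut circle concentric
with it, and a yellow stripe on the forward-facing edge so tags are glued on
the bee facing the right way.  The plotter's cutting precision bounds how
tightly circles may pack: adjacent cut circles keep at least ``clearance_mm``
between rims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .layout import TagLayout, TagSpec, load_default_layout
from .render import render_tag

__all__ = ["SheetPlacement", "layout_sheet", "make_sheet"]

MM_PER_INCH = 25.4
#: the cutting machine's stated precision
MIN_CLEARANCE_MM = 0.1


@dataclass(frozen=True)
class SheetPlacement:
    """One tag's position on the sheet (mm, center coordinates)."""

    spec: TagSpec
    cx_mm: float
    cy_mm: float


def layout_sheet(
    specs: Sequence[TagSpec],
    columns: int = 10,
    pitch_mm: float | None = None,
    margin_mm: float = 5.0,
    clearance_mm: float = 0.5,
) -> tuple[list[SheetPlacement], float, float]:
    """Place tags on a row-major grid; returns (placements, width_mm, height_mm).

    *pitch_mm* defaults to the largest cut diameter plus *clearance_mm*.  A
    pitch that brings cut circles within the machine precision of each other
    is an error.
    """
    if columns < 1:
        raise ValueError("columns must be >= 1")
    if not specs:
        return [], 2 * margin_mm, 2 * margin_mm
    max_cut = max(s.cut_diameter_mm for s in specs)
    if pitch_mm is None:
        pitch_mm = max_cut + clearance_mm
    if pitch_mm < max_cut + MIN_CLEARANCE_MM:
        raise ValueError(
            f"pitch {pitch_mm} mm leaves < {MIN_CLEARANCE_MM} mm between cut "
            f"circles of diameter {max_cut} mm"
        )
    placements = []
    for i, spec in enumerate(specs):
        row, col = divmod(i, columns)
        placements.append(
            SheetPlacement(
                spec=spec,
                cx_mm=margin_mm + max_cut / 2 + col * pitch_mm,
                cy_mm=margin_mm + max_cut / 2 + row * pitch_mm,
            )
        )
    n_rows = math.ceil(len(specs) / columns)
    n_cols = min(len(specs), columns)
    width = 2 * margin_mm + max_cut + (n_cols - 1) * pitch_mm
    height = 2 * margin_mm + max_cut + (n_rows - 1) * pitch_mm
    return placements, width, height


def _svg_tag(layout: TagLayout, p: SheetPlacement) -> list[str]:
    spec = p.spec
    side = spec.tag_side_mm
    cell = side / layout.size
    x0 = p.cx_mm - side / 2
    y0 = p.cy_mm - side / 2
    parts = [
        f'<rect x="{x0:.4f}" y="{y0:.4f}" width="{side:.4f}" '
        f'height="{side:.4f}" fill="white"/>'
    ]
    bits = layout.data_bits(spec.codeword)
    for r, row in enumerate(layout.grid):
        for c, role in enumerate(row):
            if role == "b" or (role == "d" and not bits[(r, c)]):
                parts.append(
                    f'<rect x="{x0 + c * cell:.4f}" y="{y0 + r * cell:.4f}" '
                    f'width="{cell:.4f}" height="{cell:.4f}" fill="black"/>'
                )
    parts.append(
        f'<circle cx="{p.cx_mm:.4f}" cy="{p.cy_mm:.4f}" '
        f'r="{spec.cut_diameter_mm / 2:.4f}" fill="none" '
        f'stroke="magenta" stroke-width="0.05"/>'
    )
    if spec.orientation_stripe:
        # forward edge = top of the printed square
        parts.append(
            f'<rect x="{x0:.4f}" y="{y0 - cell / 2:.4f}" width="{side:.4f}" '
            f'height="{cell / 2:.4f}" fill="yellow"/>'
        )
    return parts


def _write_svg(
    layout: TagLayout, placements, width_mm: float, height_mm: float, path: Path
) -> None:
    body = []
    for p in placements:
        body.extend(_svg_tag(layout, p))
    doc = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width_mm:.3f}mm" '
        f'height="{height_mm:.3f}mm" '
        f'viewBox="0 0 {width_mm:.3f} {height_mm:.3f}">\n'
        + "\n".join(body)
        + "\n</svg>\n"
    )
    path.write_text(doc, encoding="utf-8")


def _write_png(
    layout: TagLayout, placements, width_mm, height_mm, path: Path, dpi: int
) -> None:
    from PIL import Image

    px_per_mm = dpi / MM_PER_INCH
    W = int(round(width_mm * px_per_mm))
    H = int(round(height_mm * px_per_mm))
    sheet = np.full((H, W), 255, dtype=np.uint8)
    for p in placements:
        side_px = int(round(p.spec.tag_side_mm * px_per_mm))
        cp = max(1, side_px // layout.size)
        tag = render_tag(layout, p.spec.codeword, cell_pixels=cp)
        # nearest-neighbour resample to the exact physical pixel size
        idx = (np.arange(side_px) * tag.shape[0] / side_px).astype(int)
        tag = tag[np.ix_(idx, idx)]
        r0 = int(round(p.cy_mm * px_per_mm - side_px / 2))
        c0 = int(round(p.cx_mm * px_per_mm - side_px / 2))
        sheet[r0 : r0 + side_px, c0 : c0 + side_px] = tag
    Image.fromarray(sheet, mode="L").save(path, dpi=(dpi, dpi))


def _write_pdf(
    layout: TagLayout, placements, width_mm, height_mm, path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Rectangle

    fig = plt.figure(figsize=(width_mm / MM_PER_INCH, height_mm / MM_PER_INCH))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, width_mm)
    ax.set_ylim(height_mm, 0)
    ax.axis("off")
    for p in placements:
        side = p.spec.tag_side_mm
        cell = side / layout.size
        x0, y0 = p.cx_mm - side / 2, p.cy_mm - side / 2
        ax.add_patch(Rectangle((x0, y0), side, side, color="white"))
        bits = layout.data_bits(p.spec.codeword)
        for r, row in enumerate(layout.grid):
            for c, role in enumerate(row):
                if role == "b" or (role == "d" and not bits[(r, c)]):
                    ax.add_patch(
                        Rectangle((x0 + c * cell, y0 + r * cell), cell, cell,
                                  color="black")
                    )
        ax.add_patch(
            Circle((p.cx_mm, p.cy_mm), p.spec.cut_diameter_mm / 2,
                   fill=False, edgecolor="magenta", linewidth=0.3)
        )
        if p.spec.orientation_stripe:
            ax.add_patch(
                Rectangle((x0, y0 - cell / 2), side, cell / 2, color="yellow")
            )
    fig.savefig(path, format="pdf")
    plt.close(fig)


def make_sheet(
    specs: Sequence[TagSpec],
    path: str | Path,
    dpi: int = 1200,
    columns: int = 10,
    pitch_mm: float | None = None,
    layout: TagLayout | None = None,
) -> Path:
    """Render a printable sheet; format chosen by suffix (.svg/.png/.pdf).

    SVG is the primary vector format (mm units, plotter-friendly); PNG embeds
    the dpi so physical size survives rasterization; PDF suits office
    printers.  *dpi* only affects raster output and must be >= 300.
    """
    if dpi < 300:
        raise ValueError("dpi must be >= 300 for printable tags")
    path = Path(path)
    layout = layout or load_default_layout()
    placements, width_mm, height_mm = layout_sheet(
        specs, columns=columns, pitch_mm=pitch_mm
    )
    if path.suffix == ".svg":
        _write_svg(layout, placements, width_mm, height_mm, path)
    elif path.suffix == ".png":
        _write_png(layout, placements, width_mm, height_mm, path, dpi)
    elif path.suffix == ".pdf":
        _write_pdf(layout, placements, width_mm, height_mm, path)
    else:
        raise ValueError(f"unsupported sheet format {path.suffix!r}")
    return path
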