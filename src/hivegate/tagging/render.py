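"""Rasterize codewords onto the cell grid, decode rasters back, and the
white-pixel dilation pre-pass that rescues tags printed with ink bleed."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .layout import TagLayout

__all__ = ["render_tag", "decode_raster", "dilate_white", "AmbiguousCellError"]

WHITE = 255
BLACK = 0
#: background gray for ignored corner cells; anything works for decoding,
#: white matches paper stock.
BACKGROUND = 255


class AmbiguousCellError(ValueError):
    """A data-cell sample fell within +/-10% of the mid-gray threshold."""


def render_tag(
    layout: TagLayout,
    codeword: int,
    cell_pixels: int = 8,
    background: int = BACKGROUND,
) -> np.ndarray:
    """Render *codeword* as an 8-bit grayscale raster, axis-aligned.

    Each grid cell becomes a ``cell_pixels`` square block: fixed cells take
    their role color, data cells are white iff their codeword bit is 1 and
    ignored cells take *background*.  Deterministic by construction.
    """
    if cell_pixels < 1:
        raise ValueError("cell_pixels must be >= 1")
    bits = layout.data_bits(codeword)  # validates the codeword range
    n = layout.size
    cells = np.empty((n, n), dtype=np.uint8)
    for r, row in enumerate(layout.grid):
        for c, role in enumerate(row):
            if role == "w":
                cells[r, c] = WHITE
            elif role == "b":
                cells[r, c] = BLACK
            elif role == "x":
                cells[r, c] = background
            else:
                cells[r, c] = WHITE if bits[(r, c)] else BLACK
    return np.kron(cells, np.ones((cell_pixels, cell_pixels), dtype=np.uint8))


def decode_raster(
    image: np.ndarray,
    layout: TagLayout,
    origin: tuple[int, int] = (0, 0),
    cell_pixels: int | None = None,
) -> int:
    """Read the codeword off an axis-aligned, unrotated tag raster.

    Samples the center pixel of each data cell and thresholds at mid-gray
    (127.5); samples within +/-10% of the threshold raise
    :class:`AmbiguousCellError`.  *origin* is the top-left pixel of the tag
    inside a larger frame; *cell_pixels* defaults to ``side // grid_size``
    for a tight crop.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel raster")
    if cell_pixels is None:
        cell_pixels = img.shape[0] // layout.size
        if cell_pixels < 1:
            raise ValueError("image too small for the layout")
    thr = 127.5
    band = 0.10 * 255
    codeword = 0
    n = layout.n_data_bits
    r0, c0 = origin
    for i, (r, c) in enumerate(layout.bit_order):
        pr = r0 + r * cell_pixels + cell_pixels // 2
        pc = c0 + c * cell_pixels + cell_pixels // 2
        v = float(img[pr, pc])
        if abs(v - thr) <= band:
            raise AmbiguousCellError(
                f"data cell ({r},{c}) sample {v:.0f} is within 10% of threshold"
            )
        if v > thr:
            codeword |= 1 << (n - 1 - i)
    return codeword


def dilate_white(image: np.ndarray, kernel_px: int = 3) -> np.ndarray:
    """Morphologically dilate bright regions with a square kernel.

    Counteracts black-ink bleeding that shrinks or swallows white cells on
    cheaply printed tags; applied before detection, and harmless to disable
    on clean prints.  Output never falls below the input pointwise.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be a positive odd integer")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel raster")
    if kernel_px == 1:
        return img.copy()
    return ndimage.grey_dilation(img, size=(kernel_px, kernel_px))
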