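"""Cell-role grid of the circular tag family and the printable tag spec.

The family is a 10x10 grid whose cells are fixed white ('w') or fixed black
('b') — together the detection border ring — data cells ('d', 44 of them,
white = bit 1) or ignored corner cells ('x') that trim the square into a
raster circle small enough for a worker bee's thorax.  The grid ships as a
versioned text file which is the single source of truth; this module only
loads and validates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["TagLayout", "TagSpec", "load_default_layout", "random_codebook"]

ROLES = frozenset("wbdx")
N_DATA_BITS = 44


@dataclass(frozen=True)
class TagLayout:
    """10x10 cell-role grid plus the bit-significance order of its data cells.

    ``bit_order[0]`` is the most significant bit of the codeword; the default
    order is a raster scan (top-left to bottom-right) of the 'd' cells.
    """

    grid: tuple[tuple[str, ...], ...]
    bit_order: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.grid)
        if n == 0 or any(len(row) != n for row in self.grid):
            raise ValueError("grid must be square")
        roles = {c for row in self.grid for c in row}
        if not roles <= ROLES:
            raise ValueError(f"unknown cell roles: {roles - ROLES}")
        raster = tuple(
            (r, c)
            for r, row in enumerate(self.grid)
            for c, role in enumerate(row)
            if role == "d"
        )
        if not self.bit_order:
            object.__setattr__(self, "bit_order", raster)
        if sorted(self.bit_order) != sorted(raster):
            raise ValueError("bit_order must be a permutation of the data cells")

    @property
    def size(self) -> int:
        return len(self.grid)

    @property
    def n_data_bits(self) -> int:
        return len(self.bit_order)

    @property
    def max_codeword(self) -> int:
        return (1 << self.n_data_bits) - 1

    def data_bits(self, codeword: int) -> dict[tuple[int, int], int]:
        """Map each data-cell position to its bit of *codeword* (MSB first)."""
        if not (0 <= codeword <= self.max_codeword):
            raise ValueError(
                f"codeword must be in [0, 2^{self.n_data_bits}), got {codeword}"
            )
        n = self.n_data_bits
        return {
            pos: (codeword >> (n - 1 - i)) & 1 for i, pos in enumerate(self.bit_order)
        }

    def role_array(self) -> np.ndarray:
        return np.array([list(row) for row in self.grid])


@dataclass(frozen=True)
class TagSpec:
    """Physical printing parameters of one tag.

    The printed square is ``tag_side_mm`` on a side; the concentric cut
    circle of ``cut_diameter_mm`` must clear the data region of the square,
    i.e. exceed the diagonal of the non-ignored core, which the corner trim
    reduces from side*sqrt(2) to the checked bound below.
    """

    codeword: int
    tag_side_mm: float = 2.0
    cut_diameter_mm: float = 2.6
    orientation_stripe: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.codeword < (1 << N_DATA_BITS)):
            raise ValueError("codeword out of 44-bit range")
        if self.tag_side_mm <= 0 or self.cut_diameter_mm <= 0:
            raise ValueError("physical dimensions must be positive")
        if self.cut_diameter_mm < self._min_cut_diameter():
            raise ValueError(
                f"cut circle ({self.cut_diameter_mm} mm) does not clear the "
                f"printed data region (needs >= {self._min_cut_diameter():.3f} mm)"
            )

    def _min_cut_diameter(self) -> float:
        # Farthest used cell corner from center: with 2-cell corner trim on a
        # 10-cell side the extreme used corner sits at (5, 3) cells from
        # center -> radius sqrt(34)/10 of the side per unit cell of 1/10.
        return 2.0 * np.hypot(5.0, 3.0) / 10.0 * self.tag_side_mm


def _parse_layout_text(text: str) -> TagLayout:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(tuple(line.split()))
    return TagLayout(grid=tuple(rows))


def load_default_layout() -> TagLayout:
    """Load the shipped circular 44-data-bit layout."""
    text = (
        resources.files("hivegate").joinpath("data/tag_layout_circle44.txt")
    ).read_text(encoding="utf-8")
    layout = _parse_layout_text(text)
    if layout.n_data_bits != N_DATA_BITS:
        raise ValueError(
            f"shipped layout has {layout.n_data_bits} data cells, expected {N_DATA_BITS}"
        )
    return layout


def load_layout(path: str | Path) -> TagLayout:
    return _parse_layout_text(Path(path).read_text(encoding="utf-8"))


def random_codebook(
    n: int,
    min_hamming: int = 12,
    seed: int | None = None,
    n_bits: int = N_DATA_BITS,
) -> list[int]:
    """Synthetic codebook: random codewords kept only if they stay at least
    *min_hamming* bits from every accepted one.

    This is a test/demo surrogate for a published family file (the published
    family was produced by an offline lexicode search); random 44-bit words
    are ~22 bits apart on average, so rejection is rare at distance 12.
    """
    rng = np.random.default_rng(seed)
    book: list[int] = []
    attempts = 0
    while len(book) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not build codebook at requested distance")
        cand = int(rng.integers(0, 1 << 32)) << (n_bits - 32) | int(
            rng.integers(0, 1 << (n_bits - 32))
        )
        if all(bin(cand ^ c).count("1") >= min_hamming for c in book):
            book.append(cand)
    return book
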