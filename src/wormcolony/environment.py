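"""The spatial food patch: construction, CSV I/O and consumption accounting.

The dwelling space is a dense W x H grid of cells, each holding a
non-negative amount of food.  Food is laid out as an isotropic 2D Gaussian
centred on the grid (the boom-and-bust food patch), or loaded from a plain
CSV table.  Every unit consumed is recorded in a ledger split by consumer
class (adult vs. larva), so food is conserved exactly:
``initial_total == remaining + consumed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np

__all__ = [
    "FoodGrid",
    "GridFormatError",
    "make_gaussian_patch",
    "read_grid",
    "write_grid",
    "consume_at",
]

#: Default patch width of the central Gaussian, in cells.  Chosen so that the
#: bulk (~84 %) of a 1e6-unit patch sits in cells holding at least the default
#: adult meal of 1,000 units: food initially in cells >= c is
#: total - 2*pi*sigma^2*c, and adults can only ever feed from such cells.
DEFAULT_SIGMA = 5.0


class GridFormatError(ValueError):
    """Raised for ragged, non-numeric or negative food-grid files."""


@dataclass
class FoodGrid:
    """Dense food grid with a consumption ledger.

    ``cells`` is an H x W float array indexed ``cells[y, x]``; the ledger
    ``consumed`` accumulates units eaten, keyed by consumer class.
    """

    cells: np.ndarray
    initial_total: float = None  # type: ignore[assignment]
    consumed: dict = field(default_factory=lambda: {"adult": 0.0, "larva": 0.0})

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.float64)
        if self.cells.ndim != 2 or self.cells.size == 0:
            raise GridFormatError("food grid must be a non-empty 2D table")
        if (self.cells < 0).any():
            y, x = np.argwhere(self.cells < 0)[0]
            raise GridFormatError(f"negative food value at row {y}, column {x}")
        if self.initial_total is None:
            self.initial_total = float(self.cells.sum())

    @property
    def width(self) -> int:
        return self.cells.shape[1]

    @property
    def height(self) -> int:
        return self.cells.shape[0]

    @property
    def remaining(self) -> float:
        return float(self.cells.sum())

    @property
    def consumed_total(self) -> float:
        return float(sum(self.consumed.values()))

    def conservation_error(self) -> float:
        """Relative food-conservation error (should stay below ~1e-6)."""
        scale = max(self.initial_total, 1.0)
        return abs(self.initial_total - self.remaining - self.consumed_total) / scale

    def copy(self) -> "FoodGrid":
        return FoodGrid(self.cells.copy(), initial_total=self.initial_total,
                        consumed=dict(self.consumed))

    def consume_at(self, x: int, y: int, demand: float,
                   consumer: str = "larva") -> Tuple[bool, float]:
        """All-or-nothing meal at cell (x, y).

        If the cell holds at least ``demand`` units the consumer is fed: the
        cell is decremented and the ledger credited under ``consumer``.
        Otherwise the consumer is starved and the cell left untouched.
        Returns ``(fed, units_consumed)``.
        """
        if demand < 0:
            raise ValueError(f"demand must be non-negative, got {demand}")
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise IndexError(f"cell ({x}, {y}) outside {self.width}x{self.height} grid")
        if demand == 0:
            return True, 0.0
        if self.cells[y, x] >= demand:
            self.cells[y, x] -= demand
            self.consumed[consumer] = self.consumed.get(consumer, 0.0) + demand
            return True, float(demand)
        return False, 0.0


def consume_at(grid: FoodGrid, x: int, y: int, demand: float,
               consumer: str = "larva") -> Tuple[bool, float]:
    """Function form of :meth:`FoodGrid.consume_at`."""
    return grid.consume_at(x, y, demand, consumer=consumer)


def make_gaussian_patch(width: int = 300, height: int = 300,
                        total_food: float = 1e6,
                        sigma: float = DEFAULT_SIGMA) -> FoodGrid:
    """Central 2D-Gaussian food patch summing exactly to ``total_food``.

    The density peaks at the centre cell ``(width // 2, height // 2)`` and is
    rescaled so the grid total equals ``total_food``.  Construction is
    deterministic in its arguments.
    """
    if width <= 0 or height <= 0:
        raise ValueError("grid dimensions must be positive")
    if total_food <= 0:
        raise ValueError("total_food must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cx, cy = width // 2, height // 2
    xs = np.arange(width, dtype=np.float64) - cx
    ys = np.arange(height, dtype=np.float64) - cy
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    cells = g * (total_food / g.sum())
    return FoodGrid(cells, initial_total=float(total_food))


def read_grid(path) -> FoodGrid:
    """Load a food grid from a dense, headerless, comma-separated table."""
    path = Path(path)
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise GridFormatError(
                    f"{path.name}: row {lineno} has {len(parts)} columns, expected {width}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad = next(i for i, p in enumerate(parts)
                           if not _is_number(p))
                raise GridFormatError(
                    f"{path.name}: non-numeric value {parts[bad]!r} at row "
                    f"{lineno}, column {bad}") from None
    if not rows:
        raise GridFormatError(f"{path.name}: empty grid file")
    cells = np.array(rows, dtype=np.float64)
    if (cells < 0).any():
        y, x = np.argwhere(cells < 0)[0]
        raise GridFormatError(f"{path.name}: negative food value at row {y}, column {x}")
    return FoodGrid(cells)


def write_grid(grid: FoodGrid, path) -> None:
    """Write the grid as a dense CSV (H rows x W columns, no header).

    Values use round-trip precision so write-then-read reproduces every
    cell exactly.
    """
    np.savetxt(path, grid.cells, delimiter=",", fmt="%.17g")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
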