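"""Partitioned 2D grid arena for the leaf-cutter foraging model.

The arena is an 11-column grid of cells stacked, bottom to top, into five
horizontal bands: the *Nest area* (7 rows, containing the single nest cell),
the *Cache area* (1 row, where dropped leaves accumulate), the *Tree area*
(the trunk, whose height sets the cost of a foraging round trip), the *Drop
area* (1 row, the treetop where carriers may release their leaf), and the
*Forage area* (7 rows of canopy with unlimited leaves).

A stated "tree height" of ``h`` counts the Drop row as the treetop, so the
trunk itself occupies ``h - 1`` interior rows and the grid has ``15 + h``
rows in total: 11x16 for the terrestrial environment (h=1), 11x25 for the
intermediate one (h=10) and 11x35 for the arboreal one (h=20).

Cells are addressed ``(column, row)``, 0-indexed, with row 0 at the bottom
(nest side) and rows increasing upward toward the canopy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

WIDTH = 11
NEST_SPAN = 7
FORAGE_SPAN = 7
NEST_CELL = (6, 3)


class Area(enum.Enum):
    """The five mutually exclusive bands of the arena."""

    NEST = "Nest"
    CACHE = "Cache"
    TREE = "Tree"
    DROP = "Drop"
    FORAGE = "Forage"


class MergedArea(enum.Enum):
    """Coarse occupancy bands: Cache counts with Nest, Drop with Forage."""

    NEST_CACHE = "Nest+Cache"
    TREE = "Tree"
    FORAGE_DROP = "Forage+Drop"


#: Fixed ordering of the merged bands in occupancy arrays, bottom to top.
MERGED_ORDER = (MergedArea.NEST_CACHE, MergedArea.TREE, MergedArea.FORAGE_DROP)


@dataclass(frozen=True)
class Arena:
    """Immutable geometry of the foraging arena for one tree height."""

    tree_height: int

    def __post_init__(self) -> None:
        if not isinstance(self.tree_height, int) or isinstance(self.tree_height, bool):
            raise TypeError("tree_height must be an integer")
        if self.tree_height < 1:
            raise ValueError(f"tree_height must be >= 1, got {self.tree_height}")

    @property
    def width(self) -> int:
        return WIDTH

    @property
    def total_rows(self) -> int:
        return 15 + self.tree_height

    @property
    def cache_row(self) -> int:
        return NEST_SPAN

    @property
    def drop_row(self) -> int:
        # trunk occupies rows cache_row+1 .. drop_row-1 (h-1 rows)
        return NEST_SPAN + self.tree_height

    @property
    def nest_cell(self) -> tuple[int, int]:
        return NEST_CELL

    @property
    def forage_rows(self) -> range:
        return range(self.drop_row + 1, self.total_rows)

    @property
    def tree_rows(self) -> range:
        return range(self.cache_row + 1, self.drop_row)

    @property
    def nest_rows(self) -> range:
        return range(0, NEST_SPAN)

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        col, row = cell
        return 0 <= col < self.width and 0 <= row < self.total_rows

    def area_of(self, cell: tuple[int, int]) -> Area:
        """Return the unique :class:`Area` containing ``cell``.

        Raises :class:`IndexError` for out-of-bounds cells.
        """
        if not self.in_bounds(cell):
            raise IndexError(
                f"cell {cell} outside {self.width} x {self.total_rows} grid"
            )
        row = cell[1]
        if row < self.cache_row:
            return Area.NEST
        if row == self.cache_row:
            return Area.CACHE
        if row < self.drop_row:
            return Area.TREE
        if row == self.drop_row:
            return Area.DROP
        return Area.FORAGE

    def merged_area_of(self, cell: tuple[int, int]) -> MergedArea:
        """Like :meth:`area_of` but with Cache folded into Nest and Drop into Forage."""
        area = self.area_of(cell)
        if area in (Area.NEST, Area.CACHE):
            return MergedArea.NEST_CACHE
        if area is Area.TREE:
            return MergedArea.TREE
        return MergedArea.FORAGE_DROP


def build_arena(tree_height: int) -> Arena:
    """Construct the arena for a given tree height (>= 1).

    ``tree_height=1`` is the terrestrial environment: no trunk rows, the Drop
    row sits directly above the Cache row.
    """
    return Arena(tree_height=tree_height)
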