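"""Per-ant state machine: movement, leaf detection and the stochastic decisions.

Each ant carries a minimal behavioural state: its cell, whether it holds a
leaf, and a goal that encodes its recent history. Three stochastic decisions
drive the collective dynamics:

* at the treetop, an empty ant forages with probability ``forage_prob``
  (default 0.95) or heads back down empty;
* a carrier moving into the Drop row releases its leaf into the cache with
  probability ``P_D`` (the drop probability);
* an empty ant that detects a cached leaf (within a Chebyshev radius of 5
  cells, surveyed from the cache row or from the trunk above it) walks to it
  and takes it with probability ``P_P`` (the pick-up probability); on a
  decline it commits to foraging and stops scanning until its next
  qualitative state change.

Carriers walk a deterministic straight line to the nest (path integration);
empty ants take a uniformly random step among the forward, forward-diagonal
and sideways neighbours (olfactory noise). All randomness flows through a
single ``rng`` exposing ``random()`` (``random.Random`` and
``numpy.random.Generator`` both qualify), consuming a documented number of
draws so runs are exactly reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .arena import Arena

DETECTION_RADIUS = 5
FORAGE_PROB = 0.95


class Goal(enum.IntEnum):
    """What an ant is currently trying to do; encodes its recent history."""

    TO_FORAGE = 0  # heading up toward the canopy
    TO_NEST = 1  # heading down toward the nest
    TO_LEAF = 2  # walking to a detected cache leaf (target set)
    TO_FORAGE_CELL = 3  # walking to a chosen canopy cell (target set)


class InternalStateError(RuntimeError):
    """An ant reached a state the model forbids (e.g. carrying but not homing)."""


@dataclass(frozen=True)
class BehaviourParams:
    """The two evolvable probabilities plus fixed behavioural constants."""

    pickup_prob: float
    drop_prob: float
    forage_prob: float = FORAGE_PROB
    detection_radius: int = DETECTION_RADIUS

    def __post_init__(self) -> None:
        bad = [
            name
            for name in ("pickup_prob", "drop_prob", "forage_prob")
            if not 0.0 <= getattr(self, name) <= 1.0
        ]
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: {bad}")
        if self.detection_radius < 0:
            raise ValueError("detection_radius must be >= 0")


class CacheState:
    """Leaf counts on the Cache row, one non-negative counter per column."""

    __slots__ = ("counts", "total")

    def __init__(self, width: int) -> None:
        self.counts = [0] * width
        self.total = 0

    def add(self, col: int) -> None:
        self.counts[col] += 1
        self.total += 1

    def take(self, col: int) -> bool:
        """Remove one leaf from ``col`` if present; return whether one was taken."""
        if self.counts[col] > 0:
            self.counts[col] -= 1
            self.total -= 1
            return True
        return False


class Ant:
    """Mutable per-ant state. Position is (col, row) with row 0 at the nest side."""

    __slots__ = ("col", "row", "carrying", "goal", "target_col", "target_row",
                 "ignore_cache")

    def __init__(self, col: int, row: int, carrying: bool = False,
                 goal: Goal = Goal.TO_FORAGE) -> None:
        self.col = col
        self.row = row
        self.carrying = carrying
        self.goal = goal
        self.target_col = -1
        self.target_row = -1
        # set when a detected leaf was declined: suppress rescanning until the
        # next qualitative state change, so P_P is drawn once per detection
        self.ignore_cache = False

    @property
    def position(self) -> tuple[int, int]:
        return (self.col, self.row)


def bernoulli_decision(rng, p: float) -> bool:
    """True with probability ``p``, consuming exactly one draw from ``rng``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return rng.random() < p


def detect_leaf(ant: Ant, cache: CacheState, arena: Arena,
                radius: int = DETECTION_RADIUS, rng=None) -> int | None:
    """Nearest cache column holding a leaf within Chebyshev ``radius`` of the ant.

    Ties at equal distance are broken uniformly at random; returns ``None``
    when no cached leaf is in range.
    """
    if cache.total == 0:
        return None
    dr = abs(ant.row - arena.cache_row)
    if dr > radius:
        return None
    counts = cache.counts
    best = radius + 1
    candidates: list[int] = []
    for col in range(arena.width):
        if counts[col] > 0:
            d = dr if dr >= abs(ant.col - col) else abs(ant.col - col)
            if d > radius:
                continue
            if d < best:
                best = d
                candidates = [col]
            elif d == best:
                candidates.append(col)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.random() * len(candidates))]


def greedy_step(col: int, row: int, target_col: int, target_row: int) -> tuple[int, int]:
    """One step of the discrete straight line toward the target.

    Each coordinate moves by the sign of its remaining difference (diagonals
    allowed), so the Chebyshev distance to the target strictly decreases.
    """
    if col < target_col:
        col += 1
    elif col > target_col:
        col -= 1
    if row < target_row:
        row += 1
    elif row > target_row:
        row -= 1
    return col, row


def step_with_leaf(ant: Ant, arena: Arena) -> tuple[int, int]:
    """Deterministic straight-line step of a carrier toward the nest cell."""
    if not ant.carrying or ant.goal != Goal.TO_NEST:
        raise InternalStateError("step_with_leaf requires a carrier homing to the nest")
    nc, nr = arena.nest_cell
    if (ant.col, ant.row) == (nc, nr):
        return ant.col, ant.row
    return greedy_step(ant.col, ant.row, nc, nr)


def random_step(col: int, row: int, dy: int, arena: Arena, rng) -> tuple[int, int]:
    """Uniform step among in-bounds {forward, two forward diagonals, left, right}.

    ``dy`` is +1 when climbing toward the canopy, -1 when descending.
    """
    width = arena.width
    rows = arena.total_rows
    fr = row + dy
    candidates = []
    if 0 <= fr < rows:
        candidates.append((col, fr))
        if col > 0:
            candidates.append((col - 1, fr))
        if col < width - 1:
            candidates.append((col + 1, fr))
    if col > 0:
        candidates.append((col - 1, row))
    if col < width - 1:
        candidates.append((col + 1, row))
    return candidates[int(rng.random() * len(candidates))]


def step_without_leaf(ant: Ant, arena: Arena, rng) -> tuple[int, int]:
    """One movement step of an empty ant.

    Directional goals take a uniform random step (up for TO_FORAGE, down for
    TO_NEST); target-cell goals take the deterministic greedy step, staying
    put on arrival.
    """
    if ant.carrying:
        raise InternalStateError("step_without_leaf requires an empty ant")
    if ant.goal in (Goal.TO_LEAF, Goal.TO_FORAGE_CELL):
        if (ant.col, ant.row) == (ant.target_col, ant.target_row):
            return ant.col, ant.row
        return greedy_step(ant.col, ant.row, ant.target_col, ant.target_row)
    dy = 1 if ant.goal == Goal.TO_FORAGE else -1
    return random_step(ant.col, ant.row, dy, arena, rng)


def transition(ant: Ant, arena: Arena, cache: CacheState,
               params: BehaviourParams, rng) -> str | None:
    """Advance one ant by one timestep: decide, move, then resolve events.

    Returns the event raised this step, if any: ``"cut"`` (leaf cut in the
    canopy), ``"drop"`` (leaf released into the cache), ``"pickup"`` (leaf
    taken from the cache) or ``"deliver"`` (leaf brought to the nest cell).
    Mutates ``ant`` and ``cache`` in place.
    """
    if ant.carrying and ant.goal != Goal.TO_NEST:
        raise InternalStateError(f"carrying ant with goal {ant.goal!r}")

    cache_row = arena.cache_row
    drop_row = arena.drop_row

    # --- decisions at the current location (empty ants only) ---
    if not ant.carrying:
        if (ant.goal == Goal.TO_FORAGE or ant.goal == Goal.TO_NEST) \
                and ant.row >= cache_row and not ant.ignore_cache:
            # the cache is surveyed from the cache row and from the trunk
            # above it (never from inside the nest), still capped by the
            # detection radius; on short trees even treetop ants can sense
            # (and re-collect) cached leaves, which is what erodes the
            # benefit of dropping in terrestrial environments
            col = detect_leaf(ant, cache, arena, params.detection_radius, rng)
            if col is not None:
                if bernoulli_decision(rng, params.pickup_prob):
                    ant.goal = Goal.TO_LEAF
                    ant.target_col = col
                    ant.target_row = cache_row
                else:
                    # declined: head for the canopy, no rescanning on the way
                    ant.goal = Goal.TO_FORAGE
                    ant.ignore_cache = True
        if ant.goal == Goal.TO_NEST and ant.row <= cache_row:
            # reached the ground without targeting a leaf: head back out
            ant.goal = Goal.TO_FORAGE
        if ant.goal == Goal.TO_FORAGE and ant.row >= drop_row:
            # treetop decision: forage, or climb back down empty
            ant.ignore_cache = False
            if bernoulli_decision(rng, params.forage_prob):
                ant.goal = Goal.TO_FORAGE_CELL
                ant.target_col = int(rng.random() * arena.width)
                forage = arena.forage_rows
                ant.target_row = forage.start + int(rng.random() * len(forage))
            else:
                ant.goal = Goal.TO_NEST

    # --- movement ---
    prev_row = ant.row
    if ant.carrying:
        ant.col, ant.row = step_with_leaf(ant, arena)
    else:
        ant.col, ant.row = step_without_leaf(ant, arena, rng)

    # --- events at the new location ---
    if ant.carrying:
        if ant.row == drop_row and prev_row > drop_row:
            if bernoulli_decision(rng, params.drop_prob):
                cache.add(ant.col)
                ant.carrying = False
                ant.goal = Goal.TO_FORAGE
                ant.ignore_cache = False
                return "drop"
        if (ant.col, ant.row) == arena.nest_cell:
            ant.carrying = False
            ant.goal = Goal.TO_FORAGE
            ant.ignore_cache = False
            return "deliver"
    elif ant.goal == Goal.TO_LEAF:
        if (ant.col, ant.row) == (ant.target_col, ant.target_row):
            if cache.take(ant.col):
                ant.carrying = True
                ant.goal = Goal.TO_NEST
                return "pickup"
            # another ant got here first: rescan from scratch next step
            ant.goal = Goal.TO_FORAGE
            ant.ignore_cache = False
    elif ant.goal == Goal.TO_FORAGE_CELL:
        if (ant.col, ant.row) == (ant.target_col, ant.target_row):
            ant.carrying = True  # unlimited leaf supply in the canopy
            ant.goal = Goal.TO_NEST
            return "cut"
    return None
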