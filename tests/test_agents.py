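"""Ant state machine: movement rules, detection, and the three decisions."""

import math
import random

import pytest

from attasim.agents import (Ant, BehaviourParams, CacheState, Goal,
                            InternalStateError, bernoulli_decision,
                            detect_leaf, step_with_leaf, step_without_leaf,
                            transition)
from attasim.arena import build_arena


def binomial_ci(p, n, z=1.96):
    half = z * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


@pytest.fixture
def rng():
    return random.Random(42)


@pytest.fixture
def arena():
    return build_arena(20)


class TestBernoulliDecision:
    def test_degenerate_probabilities(self, rng):
        assert not any(bernoulli_decision(rng, 0.0) for _ in range(1000))
        assert all(bernoulli_decision(rng, 1.0) for _ in range(1000))

    def test_empirical_frequency_within_ci(self, rng):
        n = 10_000
        hits = sum(bernoulli_decision(rng, 0.95) for _ in range(n))
        lo, hi = binomial_ci(0.95, n)
        assert lo <= hits / n <= hi

    @pytest.mark.parametrize("p", [-0.1, 1.1, 2.0])
    def test_invalid_probability_rejected(self, rng, p):
        with pytest.raises(ValueError):
            bernoulli_decision(rng, p)

    def test_consumes_exactly_one_draw(self):
        a, b = random.Random(7), random.Random(7)
        bernoulli_decision(a, 0.5)
        b.random()
        assert a.random() == b.random()


class TestBehaviourParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(pickup_prob=-0.1, drop_prob=0.5),
         dict(pickup_prob=0.5, drop_prob=1.5),
         dict(pickup_prob=0.5, drop_prob=0.5, forage_prob=2.0),
         dict(pickup_prob=0.5, drop_prob=0.5, detection_radius=-1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BehaviourParams(**kwargs)

    def test_defaults(self):
        params = BehaviourParams(0.3, 0.7)
        assert params.forage_prob == 0.95
        assert params.detection_radius == 5


class TestDetectLeaf:
    def test_leaf_at_radius_boundary_found(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(5)
        # ant on the cache row, 5 columns away: Chebyshev distance 5
        ant = Ant(col=0, row=arena.cache_row)
        assert detect_leaf(ant, cache, arena, radius=5, rng=rng) == 5

    def test_leaf_beyond_radius_missed(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(6)
        ant = Ant(col=0, row=arena.cache_row)
        assert detect_leaf(ant, cache, arena, radius=5, rng=rng) is None

    def test_vertical_distance_counts(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(6)
        # 6 rows above the cache: out of range even in the same column
        ant = Ant(col=6, row=arena.cache_row + 6)
        assert detect_leaf(ant, cache, arena, radius=5, rng=rng) is None
        ant.row = arena.cache_row + 5
        assert detect_leaf(ant, cache, arena, radius=5, rng=rng) == 6

    def test_empty_cache_gives_nothing(self, arena, rng):
        ant = Ant(col=5, row=arena.cache_row)
        assert detect_leaf(ant, CacheState(arena.width), arena, 5, rng) is None

    def test_nearest_leaf_preferred(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(2)
        cache.add(9)
        ant = Ant(col=3, row=arena.cache_row)
        assert detect_leaf(ant, cache, arena, radius=5, rng=rng) == 2

    def test_equidistant_ties_broken_uniformly(self, arena):
        # brute-force candidate set: columns 3 and 7 both at distance 2
        cache = CacheState(arena.width)
        cache.add(3)
        cache.add(7)
        rng = random.Random(0)
        ant = Ant(col=5, row=arena.cache_row)
        n = 10_000
        picks = sum(detect_leaf(ant, cache, arena, 5, rng) == 3 for _ in range(n))
        lo, hi = binomial_ci(0.5, n)
        assert lo <= picks / n <= hi


class TestStepWithLeaf:
    def test_straight_down_same_column(self, arena):
        for k in (5, 10, 20):
            ant = Ant(col=6, row=k, carrying=True, goal=Goal.TO_NEST)
            assert step_with_leaf(ant, arena) == (6, k - 1)

    def test_diagonal_step_matches_sign_oracle(self, arena):
        # oracle: each coordinate moves by the sign of its remaining difference
        ant = Ant(col=9, row=7, carrying=True, goal=Goal.TO_NEST)
        assert step_with_leaf(ant, arena) == (8, 6)

    def test_exhaustive_against_sign_oracle(self, arena):
        nc, nr = arena.nest_cell
        for col in range(arena.width):
            for row in range(arena.total_rows):
                ant = Ant(col=col, row=row, carrying=True, goal=Goal.TO_NEST)
                expect = (col + (nc > col) - (nc < col), row + (nr > row) - (nr < row))
                assert step_with_leaf(ant, arena) == expect

    def test_at_nest_stays_put(self, arena):
        ant = Ant(col=6, row=3, carrying=True, goal=Goal.TO_NEST)
        assert step_with_leaf(ant, arena) == (6, 3)

    def test_requires_carrier(self, arena):
        ant = Ant(col=5, row=5, carrying=False, goal=Goal.TO_NEST)
        with pytest.raises(InternalStateError):
            step_with_leaf(ant, arena)


class TestStepWithoutLeaf:
    def test_interior_ascent_uniform_over_five_candidates(self, arena):
        rng = random.Random(1)
        counts = {}
        n = 10_000
        for _ in range(n):
            ant = Ant(col=5, row=10, goal=Goal.TO_FORAGE)
            pos = step_without_leaf(ant, arena, rng)
            counts[pos] = counts.get(pos, 0) + 1
        expected = {(5, 11), (4, 11), (6, 11), (4, 10), (6, 10)}
        assert set(counts) == expected
        lo, hi = binomial_ci(0.2, n)
        for c in counts.values():
            assert lo <= c / n <= hi

    def test_wall_restricts_to_in_bounds_candidates(self, arena):
        rng = random.Random(2)
        seen = set()
        for _ in range(2000):
            ant = Ant(col=0, row=10, goal=Goal.TO_FORAGE)
            seen.add(step_without_leaf(ant, arena, rng))
        assert seen == {(0, 11), (1, 11), (1, 10)}

    def test_descent_moves_down(self, arena):
        rng = random.Random(3)
        for _ in range(200):
            ant = Ant(col=5, row=10, goal=Goal.TO_NEST)
            col, row = step_without_leaf(ant, arena, rng)
            assert row in (9, 10)
            assert abs(col - 5) <= 1

    def test_target_goal_steps_greedily(self, arena):
        ant = Ant(col=2, row=10, goal=Goal.TO_LEAF)
        ant.target_col, ant.target_row = 6, arena.cache_row
        rng = random.Random(4)
        assert step_without_leaf(ant, arena, rng) == (3, 9)

    def test_arrival_at_target_stays_put(self, arena):
        ant = Ant(col=6, row=arena.cache_row, goal=Goal.TO_LEAF)
        ant.target_col, ant.target_row = 6, arena.cache_row
        assert step_without_leaf(ant, arena, random.Random(5)) == (6, arena.cache_row)

    def test_chebyshev_speed_at_most_one(self, arena):
        rng = random.Random(6)
        for goal in (Goal.TO_FORAGE, Goal.TO_NEST):
            for _ in range(500):
                col, row = rng.randrange(11), rng.randrange(arena.total_rows)
                ant = Ant(col=col, row=row, goal=goal)
                nc, nr = step_without_leaf(ant, arena, rng)
                assert max(abs(nc - col), abs(nr - row)) <= 1


class TestTransition:
    def params(self, pp=0.0, pd=0.0, forage=0.95):
        return BehaviourParams(pickup_prob=pp, drop_prob=pd, forage_prob=forage)

    def test_certain_drop_fills_cache_and_frees_ant(self, arena, rng):
        cache = CacheState(arena.width)
        ant = Ant(col=4, row=arena.drop_row + 1, carrying=True, goal=Goal.TO_NEST)
        event = transition(ant, arena, cache, self.params(pd=1.0), rng)
        assert event == "drop"
        # the leaf lands in the cache column directly below the drop point
        assert cache.total == 1 and cache.counts[ant.col] == 1
        assert ant.row == arena.drop_row
        assert not ant.carrying
        assert ant.goal == Goal.TO_FORAGE

    def test_certain_keep_passes_drop_row_carrying(self, arena, rng):
        cache = CacheState(arena.width)
        ant = Ant(col=4, row=arena.drop_row + 1, carrying=True, goal=Goal.TO_NEST)
        event = transition(ant, arena, cache, self.params(pd=0.0), rng)
        assert event is None
        assert cache.total == 0
        assert ant.carrying
        assert ant.row == arena.drop_row

    def test_drop_decision_only_on_first_entry(self, arena, rng):
        # a carrier already below the drop row never re-draws P_D
        cache = CacheState(arena.width)
        ant = Ant(col=6, row=arena.drop_row - 1, carrying=True, goal=Goal.TO_NEST)
        event = transition(ant, arena, cache, self.params(pd=1.0), rng)
        assert event is None
        assert ant.carrying and cache.total == 0

    def test_forage_decision_frequency(self, arena):
        rng = random.Random(11)
        n = 10_000
        went_up = 0
        for _ in range(n):
            ant = Ant(col=5, row=arena.drop_row, goal=Goal.TO_FORAGE)
            transition(ant, arena, CacheState(arena.width), self.params(), rng)
            # success: heading to a canopy cell, or already cut on arrival
            went_up += ant.goal == Goal.TO_FORAGE_CELL or ant.carrying
        lo, hi = binomial_ci(0.95, n)
        assert lo <= went_up / n <= hi

    def test_forage_decline_descends_empty(self, arena, rng):
        ant = Ant(col=5, row=arena.drop_row, goal=Goal.TO_FORAGE)
        transition(ant, arena, CacheState(arena.width), self.params(forage=0.0), rng)
        assert ant.goal == Goal.TO_NEST
        assert not ant.carrying

    def test_forage_target_lies_in_canopy(self, arena):
        rng = random.Random(12)
        for _ in range(500):
            ant = Ant(col=5, row=arena.drop_row, goal=Goal.TO_FORAGE)
            transition(ant, arena, CacheState(arena.width), self.params(forage=1.0), rng)
            # target is a canopy cell (the ant may already have reached an
            # adjacent target and cut, in which case it is homing)
            assert ant.goal == Goal.TO_FORAGE_CELL or ant.carrying
            assert ant.target_row in arena.forage_rows
            assert 0 <= ant.target_col < arena.width

    def test_cut_on_arrival_at_forage_target(self, arena, rng):
        ant = Ant(col=5, row=arena.drop_row + 2, goal=Goal.TO_FORAGE_CELL)
        ant.target_col, ant.target_row = 5, arena.drop_row + 3
        event = transition(ant, arena, CacheState(arena.width), self.params(), rng)
        assert event == "cut"
        assert ant.carrying
        assert ant.goal == Goal.TO_NEST

    def test_delivery_at_nest_cell(self, arena, rng):
        ant = Ant(col=6, row=4, carrying=True, goal=Goal.TO_NEST)
        event = transition(ant, arena, CacheState(arena.width), self.params(), rng)
        assert event == "deliver"
        assert ant.position == arena.nest_cell
        assert not ant.carrying
        assert ant.goal == Goal.TO_FORAGE

    def test_certain_pickup_targets_and_takes_leaf(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(6)
        ant = Ant(col=6, row=arena.cache_row + 1, goal=Goal.TO_NEST)
        event = transition(ant, arena, cache, self.params(pp=1.0), rng)
        assert ant.goal in (Goal.TO_LEAF, Goal.TO_NEST)
        # one more step reaches the leaf cell and picks it up
        if event != "pickup":
            event = transition(ant, arena, cache, self.params(pp=1.0), rng)
        assert event == "pickup"
        assert ant.carrying and ant.goal == Goal.TO_NEST
        assert cache.total == 0

    def test_declined_leaf_not_rescanned(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(6)
        ant = Ant(col=6, row=arena.cache_row, goal=Goal.TO_FORAGE)
        transition(ant, arena, cache, self.params(pp=0.0), rng)
        assert ant.goal == Goal.TO_FORAGE
        assert ant.ignore_cache
        # subsequent steps keep climbing without re-drawing P_P
        for _ in range(3):
            transition(ant, arena, cache, self.params(pp=1.0), rng)
            assert ant.goal in (Goal.TO_FORAGE, Goal.TO_FORAGE_CELL)
        assert cache.total == 1

    def test_contention_only_first_arrival_takes_leaf(self, arena, rng):
        cache = CacheState(arena.width)
        cache.add(5)
        ants = [Ant(col=5, row=arena.cache_row, goal=Goal.TO_FORAGE)
                for _ in range(2)]
        events = [transition(a, arena, cache, self.params(pp=1.0), rng)
                  for a in ants]
        assert events.count("pickup") == 1
        assert cache.total == 0
        loser = ants[events.index(None)]
        assert not loser.carrying

    def test_nest_scanning_suppressed_below_cache_row(self, arena, rng):
        # ants inside the nest area do not survey the cache
        cache = CacheState(arena.width)
        cache.add(6)
        ant = Ant(col=6, row=arena.cache_row - 1, goal=Goal.TO_FORAGE)
        transition(ant, arena, cache, self.params(pp=1.0), rng)
        assert ant.goal == Goal.TO_FORAGE
        assert cache.total == 1

    def test_inconsistent_carrier_state_rejected(self, arena, rng):
        ant = Ant(col=5, row=5, carrying=True, goal=Goal.TO_FORAGE)
        with pytest.raises(InternalStateError):
            transition(ant, arena, CacheState(arena.width), self.params(), rng)

    def test_no_drops_means_cache_stays_empty(self, arena):
        # P_P = P_D = 0: no leaf is ever dropped, for any seed
        for seed in range(5):
            rng = random.Random(seed)
            cache = CacheState(arena.width)
            ants = [Ant(col=rng.randrange(11), row=rng.randrange(arena.total_rows))
                    for _ in range(10)]
            for _ in range(300):
                for ant in ants:
                    transition(ant, arena, cache, self.params(), rng)
                assert cache.total == 0

    def test_carrier_approaches_nest_monotonically(self, arena):
        rng = random.Random(13)
        nc, nr = arena.nest_cell
        ant = Ant(col=10, row=arena.total_rows - 1, carrying=True, goal=Goal.TO_NEST)
        params = self.params(pd=0.0)
        dist = max(abs(ant.col - nc), abs(ant.row - nr))
        while ant.position != arena.nest_cell:
            transition(ant, arena, CacheState(arena.width), params, rng)
            new_dist = max(abs(ant.col - nc), abs(ant.row - nr))
            assert new_dist == dist - 1
            dist = new_dist
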