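"""Run one colony for T timesteps; compute fitness; collect observables.

A colony is ``n_ants`` foragers (default 25) sharing one arena and one leaf
cache, stepped for ``t_max`` timesteps (default 10,000). Each timestep every
ant acts exactly once in a freshly randomized activation order; cache
mutations are visible immediately within the step, which resolves pick-up
contention in activation order. Colony fitness is

    omega = W - c * P_P

where ``W`` is the number of leaves delivered to the nest cell, ``P_P`` the
pick-up probability and ``c`` a cost coefficient (default 0.3) charging the
colony for time spent searching the cache.

Per-timestep observables are recorded after all ants have moved: ant counts
per merged area (Nest+Cache, Tree, Forage+Drop) and the total cache size.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agents import Ant, BehaviourParams, CacheState, transition
from .arena import MERGED_ORDER, build_arena

logger = logging.getLogger(__name__)

#: column order of occupancy arrays, matching MERGED_ORDER
AREA_NAMES = tuple(m.value for m in MERGED_ORDER)

DEFAULT_N_ANTS = 25
DEFAULT_T_MAX = 10_000
DEFAULT_COST = 0.3


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterisation of one colony run."""

    tree_height: int
    behaviour: BehaviourParams
    n_ants: int = DEFAULT_N_ANTS
    t_max: int = DEFAULT_T_MAX
    cost_coefficient: float = DEFAULT_COST
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.cost_coefficient < 0:
            raise ValueError("cost_coefficient must be >= 0")


@dataclass
class SimulationResult:
    """Outcome of one colony run.

    ``occupancy`` has shape ``(t_max, 3)`` with columns ordered as
    :data:`AREA_NAMES`; ``cache_series`` has shape ``(t_max,)``.
    """

    params: SimulationParams
    W: int
    omega: float
    occupancy: np.ndarray
    cache_series: np.ndarray
    leaves_cut: int
    seed: int | None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (
            self.params == other.params
            and self.W == other.W
            and self.omega == other.omega
            and self.leaves_cut == other.leaves_cut
            and self.seed == other.seed
            and np.array_equal(self.occupancy, other.occupancy)
            and np.array_equal(self.cache_series, other.cache_series)
        )


def compute_fitness(W: float, pickup_prob: float, cost_coefficient: float = DEFAULT_COST) -> float:
    """Colony fitness omega = W - c * P_P."""
    if W < 0:
        raise ValueError("W must be >= 0")
    if not 0.0 <= pickup_prob <= 1.0:
        raise ValueError("pickup_prob must be in [0, 1]")
    if cost_coefficient < 0:
        raise ValueError("cost_coefficient must be >= 0")
    return W - cost_coefficient * pickup_prob


def run_colony(params: SimulationParams, *, record: bool = True,
               check_conservation: bool = False) -> SimulationResult:
    """Execute one colony simulation, deterministically for a fixed seed.

    All stochastic draws (initial placement, activation order, Bernoulli
    decisions, movement, forage targets) consume a single per-run RNG in a
    fixed order, so identical parameters and seed give identical results.

    ``record=False`` skips the occupancy and cache time series (the arrays
    come back empty), which is what the landscape sweep uses.
    ``check_conservation=True`` asserts leaf conservation
    (cut == carried + cached + delivered) after every timestep.
    """
    arena = build_arena(params.tree_height)
    behaviour = params.behaviour
    rng = random.Random(params.seed)
    width, rows = arena.width, arena.total_rows

    # ants start at uniformly random cells, empty, heading for the canopy
    ants = [
        Ant(col=int(rng.random() * width), row=int(rng.random() * rows))
        for _ in range(params.n_ants)
    ]
    cache = CacheState(width)
    W = 0
    cut = 0
    t_max = params.t_max
    if record:
        occupancy = np.zeros((t_max, 3), dtype=np.int64)
        cache_series = np.zeros(t_max, dtype=np.int64)
    else:
        occupancy = np.zeros((0, 3), dtype=np.int64)
        cache_series = np.zeros(0, dtype=np.int64)

    order = list(range(params.n_ants))
    cache_row = arena.cache_row
    drop_row = arena.drop_row
    for t in range(t_max):
        rng.shuffle(order)
        for i in order:
            event = transition(ants[i], arena, cache, behaviour, rng)
            if event is not None:
                if event == "deliver":
                    W += 1
                elif event == "cut":
                    cut += 1
        if record:
            n_ground = n_tree = 0
            for ant in ants:
                if ant.row <= cache_row:
                    n_ground += 1
                elif ant.row < drop_row:
                    n_tree += 1
            occupancy[t, 0] = n_ground
            occupancy[t, 1] = n_tree
            occupancy[t, 2] = params.n_ants - n_ground - n_tree
            cache_series[t] = cache.total
        if check_conservation:
            carried = sum(1 for ant in ants if ant.carrying)
            if cut != carried + cache.total + W:
                raise AssertionError(
                    f"leaf conservation violated at t={t}: cut={cut}, "
                    f"carried={carried}, cached={cache.total}, delivered={W}"
                )

    omega = compute_fitness(W, behaviour.pickup_prob, params.cost_coefficient)
    return SimulationResult(
        params=params, W=W, omega=omega, occupancy=occupancy,
        cache_series=cache_series, leaves_cut=cut, seed=params.seed,
    )


def run_replicates(params: SimulationParams, n_replicates: int,
                   base_seed: int | None = None, *, record: bool = True) -> list[SimulationResult]:
    """Run ``n_replicates`` colonies differing only in seed.

    Replicate ``r`` uses seed ``base_seed + r`` (or the params seed when
    ``base_seed`` is None and the params carry one).
    """
    if base_seed is None:
        base_seed = params.seed if params.seed is not None else 0
    results = []
    for r in range(n_replicates):
        p = replace(params, seed=base_seed + r)
        logger.info("replicate %d/%d starting (seed=%d)", r + 1, n_replicates, p.seed)
        res = run_colony(p, record=record)
        logger.info("replicate %d/%d done: W=%d omega=%.2f", r + 1, n_replicates, res.W, res.omega)
        results.append(res)
    return results


def occupancy_summary(results: list[SimulationResult], t_window: int) -> pd.DataFrame:
    """Replicate mean and SD of ant counts per merged area over the first
    ``t_window`` timesteps.

    All results must share parameters except the seed. Returns a tidy frame
    with columns ``t, area, mean_count, sd_count`` (SD is the population SD;
    0 for a single replicate).
    """
    if not results:
        raise ValueError("no results given")
    ref = replace(results[0].params, seed=None)
    for res in results[1:]:
        if replace(res.params, seed=None) != ref:
            raise ValueError("results have heterogeneous parameters")
    if t_window > ref.t_max:
        raise ValueError(f"t_window {t_window} exceeds t_max {ref.t_max}")
    stack = np.stack([res.occupancy[:t_window] for res in results])  # (reps, t, 3)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    records = []
    for ai, area in enumerate(AREA_NAMES):
        for t in range(t_window):
            records.append((t, area, mean[t, ai], sd[t, ai]))
    return pd.DataFrame(records, columns=["t", "area", "mean_count", "sd_count"])


def occupancy_frame(results: list[SimulationResult]) -> pd.DataFrame:
    """Tidy per-replicate occupancy: columns replicate, t, area, count."""
    frames = []
    for r, res in enumerate(results):
        t = np.arange(res.occupancy.shape[0])
        for ai, area in enumerate(AREA_NAMES):
            frames.append(pd.DataFrame(
                {"replicate": r, "t": t, "area": area, "count": res.occupancy[:, ai]}
            ))
    return pd.concat(frames, ignore_index=True)


def cache_frame(results: list[SimulationResult]) -> pd.DataFrame:
    """Tidy per-replicate cache size: columns replicate, t, cache_size."""
    frames = []
    for r, res in enumerate(results):
        frames.append(pd.DataFrame({
            "replicate": r,
            "t": np.arange(res.cache_series.shape[0]),
            "cache_size": res.cache_series,
        }))
    return pd.concat(frames, ignore_index=True)


def result_frame(results: list[SimulationResult]) -> pd.DataFrame:
    """One row per replicate: replicate, seed, W, omega."""
    return pd.DataFrame({
        "replicate": np.arange(len(results)),
        "seed": [res.seed for res in results],
        "W": [res.W for res in results],
        "omega": [res.omega for res in results],
    })
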