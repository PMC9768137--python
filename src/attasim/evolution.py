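"""Haploid two-locus evolution of colony genotypes on a fitness landscape.

A population of colonies (default 50), each characterised by a genotype
``(P_P, P_D)``, evolves in non-overlapping generations of constant size.
Every generation each colony's fitness is read off a precomputed,
bilinearly interpolated fitness landscape — no fresh agent simulations.
Colonies reproduce sexually in proportion to fitness: for each offspring,
two parents are drawn independently with probability proportional to
``max(omega, 0)`` (uniformly if every weight is zero), and each locus is
inherited from one of the two parents by a fair coin, independently per
locus (unlinked loci). Each inherited locus then mutates with probability
0.01 by adding a N(0, 0.1) deviate, clipped to [0, 1].

The summary statistic tracked over evolutionary time is the degree of task
partitioning, (P_P + P_D) / 2: 0 is the fully generalist corner, 1 the
fully task-partitioned corner.

Genotype populations are plain ``(n, 2)`` float arrays with columns
``(P_P, P_D)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import FitnessLandscape

DEFAULT_POPULATION = 50
DEFAULT_GENERATIONS = 10_000
DEFAULT_MUTATION_RATE = 0.01
DEFAULT_MUTATION_SD = 0.1
DEFAULT_INIT_RANGE = (0.0, 0.2)


@dataclass(frozen=True)
class EvolutionParams:
    population: int = DEFAULT_POPULATION
    generations: int = DEFAULT_GENERATIONS
    mutation_rate: float = DEFAULT_MUTATION_RATE
    mutation_sd: float = DEFAULT_MUTATION_SD
    init_range: tuple[float, float] = DEFAULT_INIT_RANGE
    thin: int = 100  # keep full genotype snapshots every `thin` generations
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.mutation_rate < 0 or self.mutation_rate > 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        lo, hi = self.init_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("init_range must satisfy 0 <= lo <= hi <= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class Trajectory:
    """Per-generation summaries of one evolutionary run (length generations+1,
    the initial population included) plus thinned genotype snapshots."""

    mean_pp: np.ndarray
    mean_pd: np.ndarray
    mean_degree: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.mean_degree)

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": replicate,
            "generation": np.arange(len(self)),
            "mean_Pp": self.mean_pp,
            "mean_Pd": self.mean_pd,
            "mean_degree": self.mean_degree,
        })

    def snapshots_frame(self, replicate: int = 0) -> pd.DataFrame:
        records = []
        for gen in sorted(self.snapshots):
            pop = self.snapshots[gen]
            for colony, (pp, pd_) in enumerate(pop):
                records.append((replicate, gen, colony, pp, pd_))
        return pd.DataFrame(records, columns=["replicate", "generation", "colony", "Pp", "Pd"])


def degree_of_task_partitioning(pp, pd=None):
    """(P_P + P_D) / 2, the degree of task partitioning in [0, 1].

    Accepts either two scalars/arrays or a single ``(n, 2)`` genotype array.
    """
    if pd is None:
        geno = np.asarray(pp, dtype=float)
        return (geno[..., 0] + geno[..., 1]) / 2.0
    return (np.asarray(pp, dtype=float) + np.asarray(pd, dtype=float)) / 2.0


def init_population(params: EvolutionParams, rng: np.random.Generator) -> np.ndarray:
    """Draw every locus i.i.d. uniform on the init range (default [0, 0.2])."""
    lo, hi = params.init_range
    return rng.uniform(lo, hi, size=(params.population, 2))


def mutate_locus(values, rate: float, sd: float, rng: np.random.Generator):
    """Mutate loci independently: with probability ``rate`` add a N(0, sd)
    deviate, then clip into [0, 1]; otherwise leave the value unchanged.

    Vectorised over arbitrarily shaped arrays; scalars return scalars.
    """
    arr = np.asarray(values, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).copy()
    mask = rng.random(arr.shape) < rate
    n_mut = int(mask.sum())
    if n_mut:
        arr[mask] = np.clip(arr[mask] + rng.normal(0.0, sd, size=n_mut), 0.0, 1.0)
    return float(arr[0]) if scalar else arr


def select_parents(fitnesses: np.ndarray, n_offspring: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample two parents per offspring, independently and with replacement,
    with probability proportional to max(fitness, 0); uniformly if all
    weights vanish. Returns an (n_offspring, 2) index array."""
    w = np.maximum(np.asarray(fitnesses, dtype=float), 0.0)
    total = w.sum()
    p = w / total if total > 0 else None
    return rng.choice(len(w), size=(n_offspring, 2), replace=True, p=p)


def inherit_loci(population: np.ndarray, parents: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Recombine unlinked loci: each offspring locus comes from one of its two
    parents, chosen by an independent fair coin per locus.

    ``parents`` is an (n_offspring, 2) array of colony indices; returns the
    (n_offspring, 2) genotype array before mutation.
    """
    population = np.asarray(population, dtype=float)
    parents = np.asarray(parents)
    n = len(parents)
    coin = rng.integers(0, 2, size=(n, 2))  # which parent donates each locus
    donor = parents[np.arange(n)[:, None], coin]  # (n, 2) colony indices
    return population[donor, [0, 1]]  # locus l copied from donor[:, l]


def next_generation(population: np.ndarray, fitnesses: np.ndarray,
                    params: EvolutionParams, rng: np.random.Generator) -> np.ndarray:
    """Produce the next (same-sized) generation by fitness-proportional
    sexual reproduction with unlinked loci, then per-locus mutation."""
    population = np.asarray(population, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != len(fitnesses):
        raise ValueError(
            f"population ({len(population)}) and fitnesses ({len(fitnesses)}) "
            "must have the same length"
        )
    n = len(population)
    parents = select_parents(fitnesses, n, rng)  # (n, 2)
    offspring = inherit_loci(population, parents, rng)
    return mutate_locus(offspring, params.mutation_rate, params.mutation_sd, rng)


def run_evolution(landscape: FitnessLandscape, params: EvolutionParams) -> Trajectory:
    """Evolve one population on a static landscape; deterministic given seed.

    Fitness is looked up once per colony per generation from the interpolated
    landscape, so landscape sampling noise is frozen across generations.
    """
    rng = np.random.default_rng(params.seed)
    pop = init_population(params, rng)
    gens = params.generations
    mean_pp = np.empty(gens + 1)
    mean_pd = np.empty(gens + 1)
    snapshots: dict[int, np.ndarray] = {}

    for g in range(gens + 1):
        mean_pp[g] = pop[:, 0].mean()
        mean_pd[g] = pop[:, 1].mean()
        if g % params.thin == 0 or g == gens:
            snapshots[g] = pop.copy()
        if g == gens:
            break
        fitnesses = landscape.interpolate(pop[:, 0], pop[:, 1])
        pop = next_generation(pop, fitnesses, params, rng)

    return Trajectory(
        mean_pp=mean_pp, mean_pd=mean_pd,
        mean_degree=(mean_pp + mean_pd) / 2.0,
        snapshots=snapshots, seed=params.seed,
    )


def run_evolution_replicates(landscape: FitnessLandscape, params: EvolutionParams,
                             n_replicates: int, base_seed: int | None = None) -> list[Trajectory]:
    """Independent evolutionary replicates, seeded base_seed, base_seed+1, ..."""
    if base_seed is None:
        base_seed = params.seed if params.seed is not None else 0
    out = []
    for r in range(n_replicates):
        p = EvolutionParams(
            population=params.population, generations=params.generations,
            mutation_rate=params.mutation_rate, mutation_sd=params.mutation_sd,
            init_range=params.init_range, thin=params.thin, seed=base_seed + r,
        )
        out.append(run_evolution(landscape, p))
    return out


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Tidy per-generation summaries: replicate, generation, mean_Pp, mean_Pd, mean_degree."""
    return pd.concat(
        [traj.to_frame(replicate=r) for r, traj in enumerate(trajectories)],
        ignore_index=True,
    )


def snapshots_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Tidy thinned genotype lists: replicate, generation, colony, Pp, Pd."""
    return pd.concat(
        [traj.snapshots_frame(replicate=r) for r, traj in enumerate(trajectories)],
        ignore_index=True,
    )
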