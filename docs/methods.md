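# Methods

## The model

`attasim` is a discrete-time, grid-based agent model of leaf-cutter ant
foraging with stigmergic task partitioning. A colony of `n_ants` foragers
(default 25) moves on an 11-column grid split, bottom to top, into a Nest
area (7 rows, with the single nest cell at column 6, row 3), a Cache row, a
trunk of `tree_height - 1` rows, a Drop row (the treetop) and a 7-row Forage
canopy; a stated tree height of `h` counts the Drop row as the treetop, so
the grid has `15 + h` rows (11×16, 11×25 and 11×35 for the terrestrial
`h = 1`, intermediate `h = 10` and arboreal `h = 20` environments).

Each ant is a state machine with a position, a carrying flag and a goal.
Ants move one cell per timestep, Chebyshev speed ≤ 1:

* **Carriers** walk the discrete straight line to the nest cell (per-axis
  sign steps, diagonals allowed), mimicking path integration. On first
  entry into the Drop row from above they release the leaf into the cache
  column below with probability `P_D`; on reaching the nest cell they
  deliver it (`W` increments) and head back out.
* **Empty ants** with a plain directional goal take a uniformly random step
  among the in-bounds subset of {forward, two forward diagonals, left,
  right} (olfactory noise; upward drift 3/5 in the interior). Empty ants
  walking to an explicit target (a detected leaf, a chosen canopy cell) step
  greedily like carriers.
* At the treetop an ascending empty ant forages with probability
  `forage_prob` (default 0.95) — it picks a uniformly random canopy cell,
  walks to it and cuts a leaf on arrival (leaf supply is unlimited) — or
  turns back down empty with probability 0.05, which lets the
  dropper/collector ratio adjust over time.
* An empty undirected ant at or above the Cache row surveys the cache: it
  detects the nearest cached leaf within a Chebyshev radius of
  `detection_radius` cells (default 5; ties broken uniformly), walks to it
  and takes it with probability `P_P`. A declined detection commits the ant
  to foraging — it stops scanning until its next qualitative state change,
  so `P_P` is drawn once per detection rather than once per step. Several
  ants may target the same leaf; the first arrival in the randomized
  activation order takes it and later arrivals rescan.

Ants are activated exactly once per timestep in a freshly shuffled order;
cache changes are visible immediately within a step. All stochastic draws
of one run (initial uniform placement, activation order, Bernoulli
decisions, movement, canopy targets) consume a single seeded RNG in a fixed
order, so runs are bit-reproducible. Leaf conservation (cut = carried +
cached + delivered) and ant conservation hold at every timestep and can be
asserted in the step loop (`check_conservation=True`).

Colony fitness after `t_max` timesteps (default 10,000) is

    ω = W − c · P_P,   c = 0.3 by default,

the delivered-leaf count minus a linear cost for the propensity to search
the cache.

### Where ants survey the cache

The detection scope was a genuinely open design choice and it decides the
model's central result. Three options were evaluated:

1. *Ground only* (Nest and Cache rows): collectors shuttle between nest and
   cache along detection-guided straight lines while never paying the
   stochastic climb, so full task partitioning beats the generalist strategy
   at **every** tree height — the terrestrial environment no longer favours
   generalists, contradicting the intended corner structure.
2. *Anywhere*: post-delivery ants re-detect from inside the nest area and
   the same shortcut survives in weaker form.
3. *Cache row and above* (chosen): the cache is visible from the cache row
   and from the trunk above it (capped by the detection radius), but not
   from inside the nest. Collectors must climb back to the cache row before
   re-engaging, and — crucially — on short trees the treetop lies within
   detection range of the cache, so a dropper immediately spots its own
   dropped leaf and re-collects it. Dropping then degenerates into a pure
   detour in terrestrial environments, while on tall trees the treetop is
   far out of range and the drop/collect relay pays off.

Under option 3 the model reproduces the full qualitative structure: mean
`W(0,0) > W(1,1)` at `h = 1`, a monotone diagonal rise to `W(1,1)` at
`h = 20`, and a task-partitioned corner that is nearly insensitive to tree
height while the generalist corner collapses with it.

## Fitness landscapes

A sweep runs `replicates` (default 10) independent colonies at every node
of a regular `(P_P, P_D)` grid (default step 0.05, 21×21 = 441 nodes) and
stores the replicate mean and SD of ω. Per-run seeds are derived with
`numpy.random.SeedSequence` from (base seed, node indices, replicate
index), so results are independent of execution order and the sweep can be
parallelised without changing any number. The node means are interpolated
bilinearly (`scipy.interpolate.RegularGridInterpolator`, exact at nodes);
"linear interpolation" on a regular 2-D grid is under-specified and
bilinear is the natural choice. Gradients use central finite differences on
interior nodes and one-sided differences at the edges (`numpy.gradient`).

## Evolutionary simulations

Populations of 50 colony genotypes `(P_P, P_D)`, initialised i.i.d. uniform
on [0, 0.2], evolve for 10,000 non-overlapping generations by default.
Fitness is looked up once per colony per generation from the static
interpolated landscape — landscape sampling noise is frozen, and no agent
simulations run during evolution. Reproduction is sexual and
fitness-proportional: each offspring draws two parents independently with
replacement, weighted by `max(ω, 0)` (uniformly if all weights vanish — ω
can only be negative when `W = 0`); the two loci are unlinked, each
inherited from one of the two parents by an independent fair coin; each
locus then mutates with probability 0.01 by adding a N(0, 0.1) deviate,
truncated to [0, 1] by clipping (clipping was chosen over resampling a
truncated normal; the boundary mass is negligible away from the edges).
The tracked statistic is the degree of task partitioning `(P_P + P_D)/2`.

Selection with `max(ω, 0)` weights, selfing, and clipping are interpretation
choices where the behaviour was under-determined; each is isolated in a
small operator function with its own tests.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_ants` | 25 | foragers per colony |
| `t_max` | 10,000 | timesteps per colony run |
| `tree_height` | — | trunk cost; 1/10/20 = terrestrial/intermediate/arboreal |
| `P_P`, `P_D` | — | pick-up and drop probabilities (the two evolvable loci) |
| `forage_prob` | 0.95 | probability of cutting at the treetop vs descending empty |
| `detection_radius` | 5 cells | Chebyshev range of cache-leaf detection |
| `c` | 0.3 | fitness cost coefficient on `P_P` |
| sweep step / replicates | 0.05 / 10 | landscape grid and averaging |
| population / generations | 50 / 10,000 | evolutionary run size |
| mutation rate / SD | 0.01 / 0.1 | per-locus mutation probability and step size |
| init range | [0, 0.2] | initial genotype distribution |

## Problem sizes used in the test suite and acceptance script

The corner-strategy comparisons run at full scale (10 replicates × 10,000
steps per corner and height). The landscape–evolution contrast runs at a
reduced scale chosen to keep the whole suite in minutes: 0.25-step grid,
3 replicates per node, 2,000-step simulations, and 20 evolutionary
replicates of 2,000 generations. One caveat of the reduced scale: with
2,000-step runs the startup transient (ants start scattered over the whole
grid) inflates mid-diagonal nodes of the *terrestrial* landscape by about
1%, flattening its lower-left region; terrestrial endpoint medians
therefore wander roughly between 0.2 and 0.4 across seeds instead of
settling tightly near the initial range, while arboreal endpoints reach
≈ 1.0 regardless. At full scale the terrestrial diagonal declines from the
generalist corner, so the flatness is an artifact of the shortened runs,
and the tests assert the seed-robust contrast (arboreal majority above 0.5,
terrestrial majority below, large median separation).

## What the model does and does not capture

The generator *is* the study system: there is no external data. Passing
tests show that the implemented mechanism — two independently evolvable
probabilities coupled through a gravity-fed cache — produces self-organised
task partitioning and its environmental dependence. They do not show that
real *Atta* colonies work this way: the model has no pheromone trails or
direct signalling, a single tree with unlimited identical leaves, constant
colony size, no load/size matching, no energetics, and monomorphic workers.
The c·P_P fitness cost is a stand-in for search effort that the spatial
model prices only partially. Movement noise is uniform over candidate
cells, not calibrated to ant locomotion data.

## Known limitations

* The exact corner values of the landscapes depend on micro-choices of the
  movement model (candidate sets, greedy targets); the qualitative corner
  ordering and its reversal with tree height are the validated claims.
* Dropped leaves stack without bound in a cache column; no decay or loss.
* `occupancy` is recorded after all ants have moved in a step; recording
  before movement would shift series by at most one step.
* The evolutionary model freezes landscape noise (as intended): rugged
  small-replicate landscapes can pin populations to interpolation artifacts
  if used with too few sweep replicates.
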