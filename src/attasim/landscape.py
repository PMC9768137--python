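"""Fitness-landscape sweeps over the (P_P, P_D) plane.

For one tree height, colony fitness is measured on a regular grid of
(pick-up probability, drop probability) combinations — by default
0, 0.05, ..., 1.0 on both axes, 441 nodes — with 10 replicate simulations
per node. Replicate means are bilinearly interpolated to give a continuous
fitness surface, which the evolutionary simulations query instead of
re-running agent simulations.

Per-run seeds are derived from the base seed and the (node, replicate)
indices, so the sweep is embarrassingly parallel and its results do not
depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .agents import BehaviourParams, DETECTION_RADIUS, FORAGE_PROB
from .colony_sim import DEFAULT_COST, DEFAULT_N_ANTS, DEFAULT_T_MAX, SimulationParams, run_colony

logger = logging.getLogger(__name__)

DEFAULT_STEP = 0.05
DEFAULT_SWEEP_REPLICATES = 10


def probability_axis(step: float = DEFAULT_STEP) -> np.ndarray:
    """Sorted probability values 0, step, ..., 1.0 (end point included)."""
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 12)


def derive_seed(base_seed: int, node_pp: int, node_pd: int, replicate: int) -> int:
    """Deterministic per-run seed keyed by node and replicate index."""
    ss = np.random.SeedSequence((int(base_seed), node_pp, node_pd, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepSchedule:
    """Grid of behaviour combinations plus the shared simulation settings."""

    tree_height: int
    pp_values: np.ndarray = field(default_factory=probability_axis)
    pd_values: np.ndarray = field(default_factory=probability_axis)
    replicates: int = DEFAULT_SWEEP_REPLICATES
    n_ants: int = DEFAULT_N_ANTS
    t_max: int = DEFAULT_T_MAX
    cost_coefficient: float = DEFAULT_COST
    forage_prob: float = FORAGE_PROB
    detection_radius: int = DETECTION_RADIUS
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.pp_values = np.asarray(self.pp_values, dtype=float)
        self.pd_values = np.asarray(self.pd_values, dtype=float)
        for name, vals in (("pp_values", self.pp_values), ("pd_values", self.pd_values)):
            if vals.ndim != 1 or len(vals) < 2:
                raise ValueError(f"{name} must be 1-D with at least 2 values")
            if not np.all(np.diff(vals) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            if vals[0] < 0 or vals[-1] > 1:
                raise ValueError(f"{name} must lie within [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_nodes(self) -> int:
        return len(self.pp_values) * len(self.pd_values)

    def params_for(self, node_pp: int, node_pd: int, replicate: int) -> SimulationParams:
        behaviour = BehaviourParams(
            pickup_prob=float(self.pp_values[node_pp]),
            drop_prob=float(self.pd_values[node_pd]),
            forage_prob=self.forage_prob,
            detection_radius=self.detection_radius,
        )
        return SimulationParams(
            tree_height=self.tree_height,
            behaviour=behaviour,
            n_ants=self.n_ants,
            t_max=self.t_max,
            cost_coefficient=self.cost_coefficient,
            seed=derive_seed(self.base_seed, node_pp, node_pd, replicate),
        )


@dataclass(eq=False)
class FitnessLandscape:
    """Replicate-averaged fitness on the regular (P_P, P_D) node grid.

    ``mean_omega[i, j]`` is the mean fitness at ``(pp_values[i], pd_values[j])``;
    ``sd_omega`` holds the population SD across replicates (0 when n=1).
    """

    tree_height: int
    pp_values: np.ndarray
    pd_values: np.ndarray
    mean_omega: np.ndarray
    sd_omega: np.ndarray
    n_reps: int

    def __post_init__(self) -> None:
        self.pp_values = np.asarray(self.pp_values, dtype=float)
        self.pd_values = np.asarray(self.pd_values, dtype=float)
        self.mean_omega = np.asarray(self.mean_omega, dtype=float)
        self.sd_omega = np.asarray(self.sd_omega, dtype=float)
        shape = (len(self.pp_values), len(self.pd_values))
        if self.mean_omega.shape != shape:
            raise ValueError(f"mean_omega must have shape {shape}")
        if np.isnan(self.mean_omega).any():
            raise ValueError("landscape grid has missing nodes")
        self._interp = RegularGridInterpolator(
            (self.pp_values, self.pd_values), self.mean_omega,
            method="linear", bounds_error=True,
        )

    def interpolate(self, pp, pd):
        """Bilinear fitness estimate at (pp, pd); exact at grid nodes.

        Accepts scalars or equally-shaped arrays; queries must lie within
        the node grid's hull (for default axes, [0, 1] x [0, 1]).
        """
        pp = np.asarray(pp, dtype=float)
        pd = np.asarray(pd, dtype=float)
        scalar = pp.ndim == 0 and pd.ndim == 0
        pp_b, pd_b = np.broadcast_arrays(pp, pd)
        pts = np.column_stack([pp_b.ravel(), pd_b.ravel()])
        if (pts < 0).any() or (pts > 1).any():
            raise ValueError("interpolation queries must lie in [0, 1]^2")
        out = self._interp(pts)
        return float(out[0]) if scalar else out.reshape(pp_b.shape)

    def gradient(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node fitness gradient (d omega/d P_P, d omega/d P_D).

        Central finite differences on interior nodes, one-sided at edges.
        """
        d_pp, d_pd = np.gradient(self.mean_omega, self.pp_values, self.pd_values)
        return d_pp, d_pd

    def to_frame(self) -> pd.DataFrame:
        """One row per node: tree_height, P_P, P_D, mean_omega, sd_omega, n_reps."""
        pp_grid, pd_grid = np.meshgrid(self.pp_values, self.pd_values, indexing="ij")
        return pd.DataFrame({
            "tree_height": self.tree_height,
            "P_P": pp_grid.ravel(),
            "P_D": pd_grid.ravel(),
            "mean_omega": self.mean_omega.ravel(),
            "sd_omega": self.sd_omega.ravel(),
            "n_reps": self.n_reps,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FitnessLandscape":
        heights = frame["tree_height"].unique()
        if len(heights) != 1:
            raise ValueError("landscape frame must cover exactly one tree height")
        pp = np.sort(frame["P_P"].unique())
        pd_ = np.sort(frame["P_D"].unique())
        pivot = frame.pivot_table(index="P_P", columns="P_D", values="mean_omega")
        sd = frame.pivot_table(index="P_P", columns="P_D", values="sd_omega")
        return cls(
            tree_height=int(heights[0]),
            pp_values=pp, pd_values=pd_,
            mean_omega=pivot.loc[pp, pd_].to_numpy(),
            sd_omega=sd.loc[pp, pd_].to_numpy(),
            n_reps=int(frame["n_reps"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path) -> "FitnessLandscape":
        return cls.from_frame(pd.read_csv(path))


def _node_mean(schedule: SweepSchedule, i: int, j: int) -> tuple[float, float]:
    omegas = np.empty(schedule.replicates)
    for r in range(schedule.replicates):
        omegas[r] = run_colony(schedule.params_for(i, j, r), record=False).omega
    return float(omegas.mean()), float(omegas.std())


def run_sweep(schedule: SweepSchedule, n_jobs: int = 1, progress: bool = False) -> FitnessLandscape:
    """Run every (P_P, P_D) node of the schedule and average over replicates.

    ``n_jobs > 1`` parallelises over nodes with joblib; results are identical
    to the serial run because each simulation's seed is derived from the node
    and replicate indices, not from scheduling order.
    """
    npp, npd = len(schedule.pp_values), len(schedule.pd_values)
    nodes = [(i, j) for i in range(npp) for j in range(npd)]
    iterator = nodes
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(nodes, desc=f"sweep h={schedule.tree_height}")
        except ImportError:  # pragma: no cover
            pass
    if n_jobs == 1:
        stats = [_node_mean(schedule, i, j) for i, j in iterator]
    else:
        from joblib import Parallel, delayed
        stats = Parallel(n_jobs=n_jobs)(
            delayed(_node_mean)(schedule, i, j) for i, j in iterator
        )
    mean = np.empty((npp, npd))
    sd = np.empty((npp, npd))
    for (i, j), (m, s) in zip(nodes, stats):
        mean[i, j] = m
        sd[i, j] = s
    logger.info("sweep h=%d done: %d nodes x %d replicates",
                schedule.tree_height, len(nodes), schedule.replicates)
    return FitnessLandscape(
        tree_height=schedule.tree_height,
        pp_values=schedule.pp_values, pd_values=schedule.pd_values,
        mean_omega=mean, sd_omega=sd, n_reps=schedule.replicates,
    )


def interpolate(landscape: FitnessLandscape, pp, pd):
    """Module-level convenience wrapper over :meth:`FitnessLandscape.interpolate`."""
    return landscape.interpolate(pp, pd)


def landscape_gradient(landscape: FitnessLandscape) -> tuple[np.ndarray, np.ndarray]:
    """Module-level convenience wrapper over :meth:`FitnessLandscape.gradient`."""
    return landscape.gradient()
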